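"""Axis-aligned 3D volume containers and NIfTI I/O.

Conventions used throughout the toolkit:

* voxel indexing is 0-based; voxel ``(i, j, k)`` sits at physical position
  ``origin_mm + (i, j, k) * spacing_mm`` in a fixed right-handed axis order
  (axis 0 = left-right, axis 1 = anterior-posterior, axis 2 =
  inferior-superior);
* all physical distances are millimetres;
* displacement fields store per-voxel 3-vectors in mm, component on the
  last axis, and define the backward-warping transform
  ``T(x) = x + u(x)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import GeometryError, ValidationError

Triple = tuple[float, float, float]

_GEOM_ATOL = 1e-6


def _as_triple(value) -> Triple:
    t = tuple(float(v) for v in value)
    if len(t) != 3:
        raise ValidationError(f"expected a length-3 sequence, got {value!r}")
    return t  # type: ignore[return-value]


@dataclass
class _Volume:
    """Shared geometry behaviour for all concrete volume types."""

    spacing_mm: Triple = field(default=(1.0, 1.0, 1.0), kw_only=True)
    origin_mm: Triple = field(default=(0.0, 0.0, 0.0), kw_only=True)

    def __post_init__(self) -> None:
        self.spacing_mm = _as_triple(self.spacing_mm)
        self.origin_mm = _as_triple(self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"spacing must be strictly positive, got {self.spacing_mm}")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self._data().shape[:3]  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def _data(self) -> np.ndarray:
        raise NotImplementedError

    def same_geometry(self, other: "_Volume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=_GEOM_ATOL)
            and np.allclose(self.origin_mm, other.origin_mm, atol=_GEOM_ATOL)
        )

    def require_same_geometry(self, other: "_Volume", what: str = "volumes") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"{what} must share one grid: "
                f"{self.shape}@{self.spacing_mm} vs {other.shape}@{other.spacing_mm}"
            )

    def world_coordinates(self) -> np.ndarray:
        """Physical voxel-centre positions, shape ``(3, *grid_shape)``, in mm."""
        axes = [
            self.origin_mm[a] + self.spacing_mm[a] * np.arange(self.shape[a])
            for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"))


@dataclass
class ImageVolume(_Volume):
    """A 3D scalar image ``I(x)`` (arbitrary intensity units)."""

    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError(f"image must be 3D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("image contains non-finite values")
        super().__post_init__()

    def _data(self) -> np.ndarray:
        return self.values

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        return replace(self, values=values)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        nib.save(nib.Nifti1Image(self.values, self.affine), str(path))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        spacing, origin = _geometry_from_affine(img.affine)
        return cls(values=np.asarray(img.dataobj, dtype=np.float64),
                   spacing_mm=spacing, origin_mm=origin)


@dataclass
class LabelVolume(_Volume):
    """Integer-coded multi-organ map ``L(x)``; 0 is background.

    ``organ_table`` maps each nonzero code to an organ name.  Codes present
    in the array but absent from the table are tolerated (they are named
    ``organ_<code>`` on demand).
    """

    codes: np.ndarray = field(default=None)  # type: ignore[assignment]
    organ_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if not np.issubdtype(self.codes.dtype, np.integer):
            rounded = np.rint(np.asarray(self.codes, dtype=np.float64))
            self.codes = rounded.astype(np.int16)
        else:
            self.codes = self.codes.astype(np.int16)
        if self.codes.ndim != 3:
            raise ValidationError(f"label map must be 3D, got shape {self.codes.shape}")
        if self.codes.min() < 0:
            raise ValidationError("label codes must be non-negative")
        self.organ_table = {int(k): str(v) for k, v in self.organ_table.items()}
        super().__post_init__()

    def _data(self) -> np.ndarray:
        return self.codes

    @property
    def present_codes(self) -> list[int]:
        return [int(c) for c in np.unique(self.codes) if c != 0]

    def organ_name(self, code: int) -> str:
        return self.organ_table.get(int(code), f"organ_{int(code)}")

    def mask(self, code: int) -> "BinaryMask":
        return BinaryMask(voxels=self.codes == int(code),
                          spacing_mm=self.spacing_mm, origin_mm=self.origin_mm)

    def with_codes(self, codes: np.ndarray) -> "LabelVolume":
        return replace(self, codes=codes)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        nib.save(nib.Nifti1Image(self.codes.astype(np.int16), self.affine), str(path))
        if self.organ_table:
            sidecar = path.with_name(_stem(path) + ".organs.json")
            sidecar.write_text(json.dumps({str(k): v for k, v in self.organ_table.items()},
                                          indent=0, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "LabelVolume":
        path = Path(path)
        img = nib.load(str(path))
        spacing, origin = _geometry_from_affine(img.affine)
        sidecar = path.with_name(_stem(path) + ".organs.json")
        table: dict[int, str] = {}
        if sidecar.exists():
            table = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
        return cls(codes=np.asarray(img.dataobj), organ_table=table,
                   spacing_mm=spacing, origin_mm=origin)


@dataclass
class BinaryMask(_Volume):
    """A single-organ {0, 1} mask on an image grid."""

    voxels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValidationError(f"mask must be 3D, got shape {self.voxels.shape}")
        super().__post_init__()

    def _data(self) -> np.ndarray:
        return self.voxels

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()

    @property
    def physical_volume_mm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3

    def centroid_mm(self) -> np.ndarray:
        if self.is_empty:
            raise ValidationError("centroid of an empty mask is undefined")
        idx = np.argwhere(self.voxels).mean(axis=0)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        nib.save(nib.Nifti1Image(self.voxels.astype(np.uint8), self.affine), str(path))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "BinaryMask":
        img = nib.load(str(path))
        spacing, origin = _geometry_from_affine(img.affine)
        return cls(voxels=np.asarray(img.dataobj) > 0, spacing_mm=spacing, origin_mm=origin)


@dataclass
class DisplacementField(_Volume):
    """Dense per-voxel displacement ``u(x)`` in mm, component on the last axis.

    The associated transform is ``T(x) = x + u(x)`` under the toolkit's
    backward-warping convention: the warped output at ``x`` samples the
    input at ``T(x)``.
    """

    vectors: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValidationError(
                f"displacement field must have shape (nx, ny, nz, 3), got {self.vectors.shape}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValidationError("displacement field contains non-finite values")
        super().__post_init__()

    def _data(self) -> np.ndarray:
        return self.vectors

    @classmethod
    def zero(cls, like: _Volume) -> "DisplacementField":
        return cls(vectors=np.zeros(like.shape + (3,)),
                   spacing_mm=like.spacing_mm, origin_mm=like.origin_mm)

    @property
    def max_magnitude_mm(self) -> float:
        return float(np.sqrt((self.vectors ** 2).sum(axis=-1)).max())

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        nib.save(nib.Nifti1Image(self.vectors, self.affine), str(path))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "DisplacementField":
        img = nib.load(str(path))
        spacing, origin = _geometry_from_affine(img.affine)
        return cls(vectors=np.asarray(img.dataobj, dtype=np.float64),
                   spacing_mm=spacing, origin_mm=origin)


@dataclass
class DoseGrid(_Volume):
    """Absorbed dose in Gy with the prescription dose (PD) attached."""

    dose_Gy: np.ndarray = field(default=None)  # type: ignore[assignment]
    prescription_Gy: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dose_Gy = np.asarray(self.dose_Gy, dtype=np.float64)
        if self.dose_Gy.ndim != 3:
            raise ValidationError(f"dose grid must be 3D, got shape {self.dose_Gy.shape}")
        if not np.all(np.isfinite(self.dose_Gy)) or self.dose_Gy.min() < 0:
            raise ValidationError("dose values must be finite and non-negative")
        if self.prescription_Gy is None or float(self.prescription_Gy) <= 0:
            raise ValidationError(f"prescription dose must be positive, got {self.prescription_Gy}")
        self.prescription_Gy = float(self.prescription_Gy)
        super().__post_init__()

    def _data(self) -> np.ndarray:
        return self.dose_Gy

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(self.dose_Gy, self.affine)
        img.header["descrip"] = f"PD={self.prescription_Gy}Gy".encode()
        nib.save(img, str(path))
        return path

    @classmethod
    def load(cls, path: str | Path, prescription_Gy: float | None = None) -> "DoseGrid":
        img = nib.load(str(path))
        spacing, origin = _geometry_from_affine(img.affine)
        if prescription_Gy is None:
            descrip = bytes(img.header["descrip"]).decode(errors="ignore")
            if descrip.startswith("PD=") and descrip.rstrip("\x00").endswith("Gy"):
                prescription_Gy = float(descrip.rstrip("\x00")[3:-2])
            else:
                raise ValidationError(f"no prescription dose stored in {path}; pass prescription_Gy")
        return cls(dose_Gy=np.asarray(img.dataobj, dtype=np.float64),
                   prescription_Gy=prescription_Gy, spacing_mm=spacing, origin_mm=origin)


def _stem(path: Path) -> str:
    """File stem with all suffixes removed (handles ``.nii.gz``)."""
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return path.stem


def _geometry_from_affine(affine: np.ndarray) -> tuple[Triple, Triple]:
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if not np.allclose(off_diag, 0, atol=1e-4):
        raise ValidationError("only axis-aligned volumes are supported")
    spacing = tuple(float(abs(rot[a, a])) for a in range(3))
    origin = tuple(float(v) for v in affine[:3, 3])
    return spacing, origin  # type: ignore[return-value]
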