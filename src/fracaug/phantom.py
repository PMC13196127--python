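"""Synthetic abdominal phantoms: images, 9-organ label maps, dose, cohorts.

Every other module in the toolkit is testable end-to-end against these
phantoms, with no external data.  The anatomy is a fixed, stylised
abdominal template scaled to the grid: solid organs (liver, kidneys,
spleen, stomach) are ellipsoids, the bowel and duodenum are bent tubes,
and the spinal canal is a posterior midline cylinder.  The layout keeps
realistic adjacency (duodenal loop next to the stomach, colon framing the
small bowel) so deformation and metric code is exercised on touching
structures, but no claim of anatomical accuracy is made.

Axis convention (see :mod:`fracaug.grid`): axis 0 left-right, axis 1
anterior-posterior (anterior = low index), axis 2 inferior-superior.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .deform import DeformParams, simulate_session
from .errors import ConfigurationError, ValidationError
from .grid import BinaryMask, DoseGrid, ImageVolume, LabelVolume
from .registry import CohortRegistry, SessionRecord
from .seeding import child_seed

logger = logging.getLogger(__name__)

DEFAULT_ORGANS: tuple[str, ...] = (
    "duodenum",
    "large_bowel",
    "small_bowel",
    "liver",
    "left_kidney",
    "right_kidney",
    "spleen",
    "stomach",
    "spinal_canal",
)

# Arbitrary MR-like intensity means per organ (the session modality's
# intensity statistics are free parameters of the phantom).
DEFAULT_ORGAN_MEANS: dict[str, float] = {
    "duodenum": 140.0,
    "large_bowel": 110.0,
    "small_bowel": 125.0,
    "liver": 180.0,
    "left_kidney": 200.0,
    "right_kidney": 205.0,
    "spleen": 170.0,
    "stomach": 130.0,
    "spinal_canal": 90.0,
}
DEFAULT_BACKGROUND_MEAN = 60.0


@dataclass(frozen=True)
class IntensityModel:
    """Per-organ mean intensity plus global noise and bias settings."""

    organ_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ORGAN_MEANS))
    background_mean: float = DEFAULT_BACKGROUND_MEAN
    noise_std: float = 5.0
    bias_amplitude: float = 0.0  # fractional amplitude of the smooth multiplicative bias

    def __post_init__(self) -> None:
        if self.noise_std < 0 or self.bias_amplitude < 0:
            raise ValidationError("noise_std and bias_amplitude must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic abdominal session image + label map."""

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    organ_set: tuple[str, ...] = DEFAULT_ORGANS
    include_right_kidney: bool = True
    intensity_model: IntensityModel = field(default_factory=IntensityModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 16 for n in self.grid_shape):
            raise ValidationError(f"grid_shape must be three axes all >= 16, got {self.grid_shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"spacing_mm must be three positive values, got {self.spacing_mm}")
        if len(set(self.organ_set)) != len(self.organ_set):
            raise ValidationError("organ_set names must be unique")
        unknown = [o for o in self.organ_set if o not in DEFAULT_ORGANS]
        if unknown:
            raise ValidationError(f"unknown organs (no template shape): {unknown}")

    @property
    def organ_codes(self) -> dict[str, int]:
        """Codes 1..N in listed order; 0 is background."""
        return {name: i + 1 for i, name in enumerate(self.organ_set)}

    @property
    def fov_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape, dtype=float) * np.asarray(self.spacing_mm)


# ---------------------------------------------------------------------------
# template geometry (fractions of the field of view)
# ---------------------------------------------------------------------------

_ELLIPSOIDS: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    # organ: (centre fractions, semi-axis fractions)
    "liver": ((0.30, 0.42, 0.66), (0.20, 0.18, 0.16)),
    "left_kidney": ((0.76, 0.66, 0.38), (0.085, 0.080, 0.120)),
    "right_kidney": ((0.24, 0.66, 0.38), (0.085, 0.080, 0.120)),
    "spleen": ((0.78, 0.50, 0.68), (0.100, 0.090, 0.100)),
    "stomach": ((0.62, 0.30, 0.66), (0.130, 0.100, 0.100)),
}

_TUBE_RADIUS_FRAC = {"duodenum": 0.040, "large_bowel": 0.048, "small_bowel": 0.048}


def _tube_curve(name: str, n: int = 200) -> np.ndarray:
    """Centreline of a tubular organ in FOV fractions, shape (n, 3)."""
    t = np.linspace(0.0, 1.0, n)
    if name == "duodenum":
        # C-loop hugging the stomach, descending slightly.
        theta = np.deg2rad(-60.0 + 240.0 * t)
        x = 0.46 + 0.09 * np.cos(theta)
        y = 0.34 + 0.09 * np.sin(theta)
        z = 0.60 - 0.15 * t
    elif name == "small_bowel":
        # Winding anterior-central loop.
        x = 0.30 + 0.35 * t
        y = 0.28 + 0.06 * np.sin(4 * np.pi * t)
        z = 0.30 + 0.05 * np.cos(3 * np.pi * t)
    elif name == "large_bowel":
        # Ascending - transverse - descending frame, anterior of the kidneys.
        seg = np.empty((n, 3))
        thirds = np.array_split(np.arange(n), 3)
        s0 = np.linspace(0, 1, len(thirds[0]))
        seg[thirds[0]] = np.stack([np.full_like(s0, 0.16), np.full_like(s0, 0.40),
                                   0.15 + 0.40 * s0], axis=1)
        s1 = np.linspace(0, 1, len(thirds[1]))
        seg[thirds[1]] = np.stack([0.16 + 0.68 * s1, 0.40 - 0.18 * np.sin(np.pi * s1),
                                   np.full_like(s1, 0.55)], axis=1)
        s2 = np.linspace(0, 1, len(thirds[2]))
        seg[thirds[2]] = np.stack([np.full_like(s2, 0.84), np.full_like(s2, 0.40),
                                   0.55 - 0.40 * s2], axis=1)
        return seg
    else:  # pragma: no cover - guarded by the organ_set validation
        raise ConfigurationError(f"no tube template for organ {name!r}")
    return np.stack([x, y, z], axis=1)


def _paint_ellipsoid(spec: PhantomSpec, centre_frac, semi_frac) -> np.ndarray:
    coords = np.indices(spec.grid_shape, dtype=float)
    centre_vox = np.asarray(centre_frac) * np.asarray(spec.grid_shape)
    semi_mm = np.asarray(semi_frac) * spec.fov_mm
    acc = np.zeros(spec.grid_shape)
    for a in range(3):
        acc += (((coords[a] - centre_vox[a]) * spec.spacing_mm[a]) / semi_mm[a]) ** 2
    return acc <= 1.0


def _paint_tube(spec: PhantomSpec, name: str) -> np.ndarray:
    curve_mm = _tube_curve(name) * spec.fov_mm
    curve_vox = np.rint(curve_mm / np.asarray(spec.spacing_mm)).astype(int)
    curve_vox = np.clip(curve_vox, 0, np.asarray(spec.grid_shape) - 1)
    seed = np.zeros(spec.grid_shape, dtype=bool)
    seed[tuple(curve_vox.T)] = True
    radius_mm = max(_TUBE_RADIUS_FRAC[name] * float(spec.fov_mm.min()),
                    1.1 * max(spec.spacing_mm))
    dist = ndimage.distance_transform_edt(~seed, sampling=spec.spacing_mm)
    return dist <= radius_mm


def _paint_cylinder(spec: PhantomSpec) -> np.ndarray:
    coords = np.indices(spec.grid_shape[:2], dtype=float)
    centre_vox = np.array([0.50, 0.86]) * np.asarray(spec.grid_shape[:2])
    radius_mm = max(0.045 * float(min(spec.fov_mm[:2])), 1.1 * max(spec.spacing_mm[:2]))
    r2 = (((coords[0] - centre_vox[0]) * spec.spacing_mm[0]) ** 2
          + ((coords[1] - centre_vox[1]) * spec.spacing_mm[1]) ** 2)
    disc = r2 <= radius_mm ** 2
    return np.repeat(disc[:, :, None], spec.grid_shape[2], axis=2)


def _organ_shape(spec: PhantomSpec, name: str) -> np.ndarray:
    if name in _ELLIPSOIDS:
        return _paint_ellipsoid(spec, *_ELLIPSOIDS[name])
    if name in _TUBE_RADIUS_FRAC:
        return _paint_tube(spec, name)
    if name == "spinal_canal":
        return _paint_cylinder(spec)
    raise ConfigurationError(f"no template shape for organ {name!r}")


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, LabelVolume]:
    """Build one synthetic session image and its multi-organ label map.

    Organs are painted in listed order with first-come priority, so organ
    codes partition the foreground; each painted organ must remain a
    nonempty 26-connected component or a :class:`ConfigurationError` names
    the first organ that cannot be placed.
    """
    codes = np.zeros(spec.grid_shape, dtype=np.int16)
    organ_codes = spec.organ_codes
    table: dict[int, str] = {}
    structure = np.ones((3, 3, 3), dtype=bool)
    for name in spec.organ_set:
        if name == "right_kidney" and not spec.include_right_kidney:
            continue
        shape = _organ_shape(spec, name) & (codes == 0)
        n_components = ndimage.label(shape, structure=structure)[1]
        if n_components != 1:
            raise ConfigurationError(
                f"cannot place organ {name!r} on grid {spec.grid_shape}: "
                f"{n_components} connected components after painting")
        code = organ_codes[name]
        codes[shape] = code
        table[code] = name

    rng = np.random.default_rng(spec.seed)
    model = spec.intensity_model
    means = np.full(len(spec.organ_set) + 1, model.background_mean)
    for name, code in organ_codes.items():
        means[code] = model.organ_means.get(name, model.background_mean)
    values = means[codes]
    if model.bias_amplitude > 0:
        values = values * _bias_field(spec.grid_shape, model.bias_amplitude, rng)
    if model.noise_std > 0:
        values = values + rng.normal(0.0, model.noise_std, size=spec.grid_shape)

    geom = dict(spacing_mm=spec.spacing_mm, origin_mm=(0.0, 0.0, 0.0))
    return (ImageVolume(values=values, **geom),
            LabelVolume(codes=codes, organ_table=table, **geom))


def _bias_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Low-order smooth multiplicative shading field around 1."""
    axes = [np.linspace(0, np.pi, n) for n in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    surface = np.zeros(shape)
    for _ in range(3):
        freq = rng.integers(1, 3, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        term = np.ones(shape)
        for a in range(3):
            term *= np.cos(freq[a] * grids[a] + phase[a])
        surface += term
    peak = np.abs(surface).max()
    if peak > 0:
        surface /= peak
    return 1.0 + amplitude * surface


def make_dose_phantom(
    labels: LabelVolume,
    target_center_mm: tuple[float, float, float],
    prescription_Gy: float = 40.0,
    *,
    target_radius_mm: float = 8.0,
    falloff_mm: float = 12.0,
    hotspot_factor: float = 1.15,
) -> DoseGrid:
    """Smooth dose grid peaked at a target, monotone along every ray.

    The dose equals ``hotspot_factor * prescription`` inside a sphere of
    ``target_radius_mm`` around the target centre and falls off as a
    Gaussian of scale ``falloff_mm`` outside it, so the maximum exceeds the
    prescription inside the target and never increases with radial
    distance from the peak.
    """
    if prescription_Gy <= 0:
        raise ValidationError(f"prescription must be positive, got {prescription_Gy}")
    coords = labels.world_coordinates()
    target = np.asarray(target_center_mm, dtype=float)
    lo = np.asarray(labels.origin_mm)
    hi = lo + (np.asarray(labels.shape) - 1) * np.asarray(labels.spacing_mm)
    if np.any(target < lo) or np.any(target > hi):
        raise ValidationError(f"target centre {tuple(target)} lies outside the grid")
    r = np.sqrt(((coords - target.reshape(3, 1, 1, 1)) ** 2).sum(axis=0))
    excess = np.maximum(r - target_radius_mm, 0.0)
    dose = hotspot_factor * prescription_Gy * np.exp(-(excess ** 2) / (2 * falloff_mm ** 2))
    return DoseGrid(dose_Gy=dose, prescription_Gy=prescription_Gy,
                    spacing_mm=labels.spacing_mm, origin_mm=labels.origin_mm)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a multi-patient, multi-session synthetic cohort.

    ``patients`` lists ``(patient_id, n_sessions)``; session 1 of each
    patient is a fresh phantom and later sessions are simulated
    inter-fraction variants of it.  Patients named in
    ``single_kidney_patients`` are built without a right kidney.
    """

    patients: tuple[tuple[str, int], ...]
    deform_params: DeformParams = field(default_factory=DeformParams)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    single_kidney_patients: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [p for p, _ in self.patients]
        if len(set(ids)) != len(ids):
            raise ValidationError("patient ids must be unique")
        if any(n < 1 for _, n in self.patients):
            raise ValidationError("every patient needs at least one session")
        unknown = set(self.single_kidney_patients) - set(ids)
        if unknown:
            raise ValidationError(f"single_kidney_patients not in cohort: {sorted(unknown)}")


def make_cohort(spec: CohortSpec, out_dir: str | Path) -> CohortRegistry:
    """Generate a cohort on disk and return its registry.

    Per patient, session 1 is a fresh phantom (patient-specific seed);
    sessions 2..n are structure-guided deformation variants of session 1,
    saved with their ground-truth labels and total DVFs.  The registry
    (also written as ``registry.json``) lists sessions in order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    patients: dict[str, list[SessionRecord]] = {}
    for patient_id, n_sessions in spec.patients:
        pseed = child_seed(spec.seed, f"patient:{patient_id}")
        pspec = replace(spec.phantom, seed=pseed,
                        include_right_kidney=patient_id not in spec.single_kidney_patients)
        image, labels = make_phantom(pspec)
        records: list[SessionRecord] = []
        sess_image, sess_labels, dvf = image, labels, None
        for session in range(1, n_sessions + 1):
            if session > 1:
                rng = np.random.default_rng(child_seed(pseed, f"session:{session}"))
                sess_image, sess_labels, dvf = simulate_session(
                    image, labels, spec.deform_params, rng)
            stem = f"{patient_id}_s{session}"
            record = SessionRecord(
                session=session,
                image=_save(sess_image, out_dir / f"{stem}_image.nii.gz"),
                labels=_save(sess_labels, out_dir / f"{stem}_labels.nii.gz"),
                dvf=_save(dvf, out_dir / f"{stem}_dvf.nii.gz") if dvf is not None else None,
            )
            records.append(record)
        patients[patient_id] = records
    registry = CohortRegistry(patients=patients)
    registry.to_json(out_dir / "registry.json")
    return registry


def _save(volume, path: Path) -> Path:
    try:
        return volume.save(path)
    except OSError as exc:  # pragma: no cover - disk-level failure
        raise ConfigurationError(f"could not write {path}: {exc}") from exc
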