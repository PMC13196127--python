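"""Structure-guided deformation simulation.

Simulates plausible inter-fraction anatomical change by drawing, for every
organ in a label map, a random similarity motion (translation, isotropic
expansion/shrinkage, rotation about the organ centroid) bounded by
user-set maxima, converting each draw into a dense, smooth displacement
vector field (DVF) localized around that organ, and composing the
per-organ fields into one total field used to warp the session image
(linear interpolation) and its labels (nearest neighbour).

Field construction for one organ works on the *inverse* motion: under the
backward-warping convention ``output(x) = input(x + u(x))``, moving an
organ by the forward similarity map ``F`` requires ``u(x) = F⁻¹(x) − x``.
That raw field is weighted by ``w(x) = exp(−d(x)² / (2·decay²))`` with
``d`` the Euclidean distance to the organ mask in mm, then Gaussian
smoothed, so the motion is exact inside the organ and fades smoothly to
zero away from it.

Fields compose so that warping once by the composed field reproduces
sequential warping: ``compose(u_a, u_b)(x) = u_b(x) + u_a(x + u_b(x))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .errors import ValidationError
from .grid import BinaryMask, DisplacementField, ImageVolume, LabelVolume

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeformParams:
    """Bounds of the per-organ uniform draws and field shape scales.

    Attributes
    ----------
    p_disp_mm:
        Maximum displacement magnitude per axis (mm); each translation
        component is drawn uniformly from ``[-p_disp_mm, p_disp_mm]``.
    p_exp, p_shrink:
        Maximum fractional expansion / shrinkage; the isotropic scale
        factor is drawn uniformly from ``[1 - p_shrink, 1 + p_exp]``.
    p_rot_deg:
        Maximum rotation angle (degrees) about the organ centroid, per
        Euler axis.
    field_smoothing_mm:
        Gaussian scale applied to the assembled field.
    influence_decay_mm:
        Decay scale of the organ's influence region.
    """

    p_disp_mm: float = 8.0
    p_exp: float = 0.15
    p_shrink: float = 0.15
    p_rot_deg: float = 8.0
    field_smoothing_mm: float = 4.0
    influence_decay_mm: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_disp_mm", "p_exp", "p_shrink", "p_rot_deg"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.p_shrink >= 1:
            raise ValidationError("p_shrink must be < 1")
        if self.field_smoothing_mm <= 0 or self.influence_decay_mm <= 0:
            raise ValidationError("smoothing and decay scales must be > 0")


@dataclass(frozen=True)
class PhiDraw:
    """One realisation of the per-organ random similarity motion."""

    translation_mm: tuple[float, float, float]
    scale_factor: float
    rotation_deg: tuple[float, float, float]

    @property
    def is_identity(self) -> bool:
        return (
            not any(self.translation_mm)
            and self.scale_factor == 1.0
            and not any(self.rotation_deg)
        )


def sample_phi_draw(params: DeformParams, rng: np.random.Generator) -> PhiDraw:
    """Draw translation, scale, and rotation uniformly within the bounds.

    The generator state advances with every call, so successive organs
    receive distinct draws even under identical parameter bounds.
    """
    translation = rng.uniform(-params.p_disp_mm, params.p_disp_mm, size=3)
    scale = rng.uniform(1.0 - params.p_shrink, 1.0 + params.p_exp)
    rotation = rng.uniform(-params.p_rot_deg, params.p_rot_deg, size=3)
    return PhiDraw(
        translation_mm=tuple(float(t) for t in translation),
        scale_factor=float(scale),
        rotation_deg=tuple(float(r) for r in rotation),
    )


def generate_label_field(
    mask: BinaryMask, draw: PhiDraw, params: DeformParams
) -> DisplacementField:
    """Dense DVF realising ``draw`` inside ``mask``, decaying away from it."""
    if mask.is_empty:
        raise ValidationError("cannot generate a deformation field for an empty organ mask")
    if draw.is_identity:
        return DisplacementField.zero(mask)

    centroid = mask.centroid_mm()
    rot = Rotation.from_euler("xyz", draw.rotation_deg, degrees=True).as_matrix()
    # Inverse of F(x) = c + s·R·(x − c) + t  is  F⁻¹(x) = c + R⁻¹·(x − t − c)/s.
    coords = mask.world_coordinates()  # (3, nx, ny, nz)
    rel = coords - (np.asarray(centroid) + np.asarray(draw.translation_mm)).reshape(3, 1, 1, 1)
    inv = np.einsum("ab,b...->a...", rot.T, rel) / draw.scale_factor
    raw = inv + np.asarray(centroid).reshape(3, 1, 1, 1) - coords

    dist = ndimage.distance_transform_edt(~mask.voxels, sampling=mask.spacing_mm)
    weight = np.exp(-(dist ** 2) / (2.0 * params.influence_decay_mm ** 2))

    sigma_vox = [params.field_smoothing_mm / s for s in mask.spacing_mm]
    vectors = np.empty(mask.shape + (3,))
    for c in range(3):
        vectors[..., c] = ndimage.gaussian_filter(raw[c] * weight, sigma=sigma_vox, mode="nearest")
    return DisplacementField(vectors=vectors, spacing_mm=mask.spacing_mm, origin_mm=mask.origin_mm)


def _sample_coordinates(field: DisplacementField) -> np.ndarray:
    """Index-space sampling coordinates of ``T(x) = x + u(x)``, shape (3, ...)."""
    idx = np.indices(field.shape, dtype=np.float64)
    for a in range(3):
        idx[a] += field.vectors[..., a] / field.spacing_mm[a]
    return idx


def compose_fields(
    accumulated: DisplacementField, next_field: DisplacementField
) -> DisplacementField:
    """Compose two displacement fields under backward warping.

    The result satisfies ``warp(I, compose(u_a, u_b)) == warp(warp(I, u_a), u_b)``
    up to interpolation: ``u(x) = u_b(x) + u_a(x + u_b(x))``, with the
    accumulated field looked up by linear interpolation (edge-clamped).
    Composing with a zero field returns the other field unchanged.
    """
    accumulated.require_same_geometry(next_field, "displacement fields")
    if not next_field.vectors.any():
        return DisplacementField(vectors=accumulated.vectors.copy(),
                                 spacing_mm=accumulated.spacing_mm,
                                 origin_mm=accumulated.origin_mm)
    coords = _sample_coordinates(next_field)
    vectors = next_field.vectors.copy()
    for c in range(3):
        vectors[..., c] += ndimage.map_coordinates(
            accumulated.vectors[..., c], coords, order=1, mode="nearest")
    return DisplacementField(vectors=vectors, spacing_mm=accumulated.spacing_mm,
                             origin_mm=accumulated.origin_mm)


def warp_image(image: ImageVolume, dvf: DisplacementField) -> ImageVolume:
    """Backward-warp an image with linear interpolation.

    Output at ``x`` samples the input at ``x + u(x)``; samples outside the
    domain take the nearest-edge value.
    """
    image.require_same_geometry(dvf, "image and field")
    if not dvf.vectors.any():
        return image.with_values(image.values.copy())
    coords = _sample_coordinates(dvf)
    warped = ndimage.map_coordinates(image.values, coords, order=1, mode="nearest")
    return image.with_values(warped)


def warp_labels(labels: LabelVolume, dvf: DisplacementField) -> LabelVolume:
    """Backward-warp a label map with nearest-neighbour interpolation."""
    labels.require_same_geometry(dvf, "labels and field")
    if not dvf.vectors.any():
        return labels.with_codes(labels.codes.copy())
    coords = _sample_coordinates(dvf)
    warped = ndimage.map_coordinates(labels.codes, coords, order=0, mode="nearest")
    return labels.with_codes(warped)


def warp_mask(mask: BinaryMask, dvf: DisplacementField) -> BinaryMask:
    """Backward-warp a binary mask with nearest-neighbour interpolation."""
    mask.require_same_geometry(dvf, "mask and field")
    coords = _sample_coordinates(dvf)
    warped = ndimage.map_coordinates(mask.voxels.astype(np.uint8), coords, order=0,
                                     mode="nearest")
    return BinaryMask(voxels=warped > 0, spacing_mm=mask.spacing_mm, origin_mm=mask.origin_mm)


def jacobian_min(dvf: DisplacementField) -> float:
    """Minimum determinant of the spatial Jacobian of ``T(x) = x + u(x)``.

    Computed with central differences in physical units; a value <= 0
    indicates the field folds space (is locally non-injective).
    """
    jac = np.empty(dvf.shape + (3, 3))
    for comp in range(3):
        grads = np.gradient(dvf.vectors[..., comp], *dvf.spacing_mm)
        for axis in range(3):
            jac[..., comp, axis] = grads[axis]
        jac[..., comp, comp] += 1.0
    det = np.linalg.det(jac)
    result = float(det.min())
    if result <= 0:
        logger.warning("displacement field folds: min Jacobian determinant %.4f", result)
    return result


def simulate_session(
    image: ImageVolume,
    labels: LabelVolume,
    params: DeformParams,
    rng: np.random.Generator,
    *,
    organ_order: list[int] | None = None,
    strict: bool = False,
) -> tuple[ImageVolume, LabelVolume, DisplacementField]:
    """Simulate one later treatment session from an image/label pair.

    Organs are visited in ascending label-code order (or ``organ_order``).
    For organ *k* the current composed field first warps its mask, a fresh
    random draw builds the organ's DVF from that warped mask, and the
    composition is updated; the image (linear) and label map (nearest) are
    each warped once by the final total field, which is returned for QA.

    With ``strict=True`` a total field whose Jacobian determinant is
    anywhere non-positive (a folding, locally non-injective warp) raises
    instead of warning.
    """
    image.require_same_geometry(labels, "image and labels")
    codes = organ_order if organ_order is not None else labels.present_codes
    if not codes:
        raise ValidationError("label map contains no organs to deform")
    logger.info("simulate_session organ order: %s", codes)

    total = DisplacementField.zero(image)
    for code in codes:
        moved_mask = warp_mask(labels.mask(code), total)
        if moved_mask.is_empty:
            logger.warning("organ %s vanished under the accumulated field; skipping",
                           labels.organ_name(code))
            continue
        draw = sample_phi_draw(params, rng)
        logger.info("organ %s draw: t=%s mm, s=%.4f, r=%s deg", labels.organ_name(code),
                    draw.translation_mm, draw.scale_factor, draw.rotation_deg)
        organ_field = generate_label_field(moved_mask, draw, params)
        # New total realises the organ's transform applied after the
        # accumulated one: T_k ∘ T_acc, i.e. sampling passes through the
        # accumulated field first.
        total = compose_fields(organ_field, total)

    if strict and jacobian_min(total) <= 0:
        raise ValidationError("simulated field folds (min Jacobian determinant <= 0)")
    return warp_image(image, total), warp_labels(labels, total), total
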