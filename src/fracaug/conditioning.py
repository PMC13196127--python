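"""Organ-conditioned dataset arrangement.

A conditional segmentation model receives three channels — a prior
session image ``I_m``, the binary mask ``L_{m,o}`` of one organ ``o`` on
that image, and the current session image ``I_n`` — and predicts the
organ's mask ``L_{n,o}`` on the current image.  This module enumerates
ordered within-patient session pairs, binarises organ channels, resamples
a patient's sessions onto a common grid, builds patient-level
leave-one-out cross-validation folds, and writes/reads a raw dataset
layout (channel-suffix file naming plus a descriptor JSON and a manifest
CSV) that a segmentation trainer can consume directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, GeometryError, ValidationError
from .grid import BinaryMask, ImageVolume, LabelVolume
from .registry import CohortRegistry

logger = logging.getLogger(__name__)

Pair = tuple[str, int, int]  # (patient_id, source session m, target session n)

CHANNEL_NAMES = ("source_image", "source_organ_mask", "target_image")


@dataclass(frozen=True)
class FoldSplit:
    """One patient-level leave-one-out fold."""

    fold_id: int
    train_patients: tuple[str, ...]
    validation_patient: str
    test_patients: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        overlap = set(self.train_patients) & {self.validation_patient} | (
            set(self.train_patients) | {self.validation_patient}) & set(self.test_patients)
        if overlap:
            raise ValidationError(f"fold {self.fold_id}: patients span splits: {sorted(overlap)}")


@dataclass(frozen=True)
class ConditionedCase:
    """One three-channel conditioned record ``[I_m, L_{m,o}, I_n]``.

    Voxel channels are attached lazily by :func:`materialize_case`; the
    ``target_label`` (``L_{n,o}``) is present for training data only.
    """

    patient_id: str
    source_session: int
    target_session: int
    organ: str
    organ_code: int
    channel_0: ImageVolume | None = None  # I_m (resampled to the target grid)
    channel_1: ImageVolume | None = None  # L_{m,o}, binary at image dtype
    channel_2: ImageVolume | None = None  # I_n
    target_label: BinaryMask | None = None  # L_{n,o}

    def __post_init__(self) -> None:
        if self.source_session == self.target_session:
            raise ValidationError("a conditioned case needs two different sessions")

    @property
    def case_id(self) -> str:
        return (f"P{self.patient_id}_s{self.source_session}to{self.target_session}"
                f"_{self.organ}")


def enumerate_pairs(
    registry: CohortRegistry,
    patient_subset: list[str] | None = None,
    scope: str = "all_ordered",
) -> list[Pair]:
    """All ordered within-patient session pairs (m, n), m != n.

    A patient with k sessions contributes k(k-1) pairs under
    ``scope="all_ordered"`` and k-1 pairs (first session as source only)
    under ``scope="first_to_rest"``.  Ordering is deterministic: patient,
    then m, then n ascending.  Patients with fewer than two sessions
    contribute no pairs (logged, not an error).
    """
    if scope not in ("all_ordered", "first_to_rest"):
        raise ValidationError(f"unknown pair scope {scope!r}")
    ids = registry.patient_ids if patient_subset is None else list(patient_subset)
    pairs: list[Pair] = []
    for pid in sorted(ids):
        sessions = sorted(r.session for r in registry.sessions(pid))
        if len(sessions) < 2:
            logger.warning("patient %s has %d session(s); no pairs emitted", pid, len(sessions))
            continue
        sources = sessions[:1] if scope == "first_to_rest" else sessions
        pairs.extend((pid, m, n) for m in sources for n in sessions if n != m)
    return pairs


def make_loocv_folds(
    registry: CohortRegistry,
    trainval_patients: list[str] | None = None,
    test_patients: list[str] | None = None,
) -> list[FoldSplit]:
    """Patient-level leave-one-out folds over the train/validation cohort.

    Each fold holds out exactly one validation patient; all of a patient's
    sessions stay on one side of the split, so no patient leaks between
    training and validation.
    """
    trainval = sorted(trainval_patients if trainval_patients is not None
                      else registry.patient_ids)
    test = tuple(sorted(test_patients)) if test_patients else ()
    unknown = set(trainval) | set(test)
    unknown -= set(registry.patient_ids)
    if unknown:
        raise ValidationError(f"patients not in registry: {sorted(unknown)}")
    if len(trainval) < 2:
        raise ValidationError("leave-one-out needs at least 2 train/validation patients")
    return [
        FoldSplit(fold_id=i,
                  train_patients=tuple(p for p in trainval if p != held_out),
                  validation_patient=held_out,
                  test_patients=test)
        for i, held_out in enumerate(trainval)
    ]


def build_conditioned_cases(
    registry: CohortRegistry,
    pairs: list[Pair],
    organ_table: dict[int, str] | None = None,
    label_loader=None,
) -> list[ConditionedCase]:
    """One metadata-only case per (pair, organ present in the source labels).

    Organs absent from a pair's source label map (for example a missing
    kidney) are skipped with a logged notice, never emitted empty.
    ``label_loader(patient_id, session) -> LabelVolume`` defaults to
    reading the registry's label files.
    """
    loader = label_loader or _registry_label_loader(registry)
    label_cache: dict[tuple[str, int], LabelVolume] = {}
    cases: list[ConditionedCase] = []
    for pid, m, n in pairs:
        key = (pid, m)
        if key not in label_cache:
            label_cache[key] = loader(pid, m)
        labels = label_cache[key]
        table = organ_table or labels.organ_table
        codes = table.keys() if table else labels.present_codes
        present = set(labels.present_codes)
        for code in sorted(codes):
            name = table.get(code) if table else None
            name = name or labels.organ_name(code)
            if code not in present:
                logger.info("pair (%s, %d->%d): organ %s absent from source labels; skipped",
                            pid, m, n, name)
                continue
            cases.append(ConditionedCase(patient_id=pid, source_session=m,
                                         target_session=n, organ=name, organ_code=code))
    return cases


def _registry_label_loader(registry: CohortRegistry):
    def load(pid: str, session: int) -> LabelVolume:
        rec = registry.record(pid, session)
        if rec.labels is None:
            raise ConfigurationError(f"registry has no label path for {pid} session {session}")
        return LabelVolume.load(rec.labels)
    return load


def materialize_case(
    case: ConditionedCase,
    registry: CohortRegistry,
    *,
    normalize: bool = False,
) -> ConditionedCase:
    """Load and attach the three channels and the training target.

    The source session is resampled onto the target session's grid (the
    session image defines the working geometry), so all channels share one
    geometry exactly.
    """
    src = registry.record(case.patient_id, case.source_session)
    tgt = registry.record(case.patient_id, case.target_session)
    source_image = ImageVolume.load(src.image)
    source_labels = LabelVolume.load(src.labels)
    target_image = ImageVolume.load(tgt.image)
    if not source_image.same_geometry(target_image):
        source_image, source_labels = resample_to_grid(source_image, source_labels, target_image)
    if normalize:
        source_image = normalize_intensity(source_image)
        target_image = normalize_intensity(target_image)
    organ_mask = source_labels.mask(case.organ_code)
    if organ_mask.is_empty:
        raise ValidationError(
            f"case {case.case_id}: organ {case.organ!r} empty after resampling")
    mask_channel = ImageVolume(values=organ_mask.voxels.astype(np.float64),
                               spacing_mm=target_image.spacing_mm,
                               origin_mm=target_image.origin_mm)
    target_label = None
    if tgt.labels is not None:
        target_label = LabelVolume.load(tgt.labels).mask(case.organ_code)
    return replace(case, channel_0=source_image, channel_1=mask_channel,
                   channel_2=target_image, target_label=target_label)


def resample_to_grid(
    moving_image: ImageVolume,
    moving_labels: LabelVolume | None,
    reference: ImageVolume,
) -> tuple[ImageVolume, LabelVolume | None]:
    """Resample an image (linear) and labels (nearest) onto a reference grid.

    The reference grid's voxel centres are mapped into the moving volume's
    index space through the physical coordinates both share; output
    geometry equals the reference exactly.  Grids that do not overlap at
    all raise a :class:`GeometryError`.
    """
    ref_coords = reference.world_coordinates()
    mov_origin = np.asarray(moving_image.origin_mm).reshape(3, 1, 1, 1)
    mov_spacing = np.asarray(moving_image.spacing_mm).reshape(3, 1, 1, 1)
    idx = (ref_coords - mov_origin) / mov_spacing
    shape = np.asarray(moving_image.shape).reshape(3, 1, 1, 1)
    inside = np.all((idx >= -0.5) & (idx <= shape - 0.5), axis=0)
    if not inside.any():
        raise GeometryError("moving and reference grids do not overlap")
    geom = dict(spacing_mm=reference.spacing_mm, origin_mm=reference.origin_mm)
    image = ImageVolume(
        values=ndimage.map_coordinates(moving_image.values, idx, order=1, mode="nearest"),
        **geom)
    labels = None
    if moving_labels is not None:
        moving_labels.require_same_geometry(moving_image, "moving image and labels")
        labels = LabelVolume(
            codes=ndimage.map_coordinates(moving_labels.codes, idx, order=0, mode="nearest"),
            organ_table=moving_labels.organ_table, **geom)
    return image, labels


def normalize_intensity(image: ImageVolume, floor_percentile: float = 5.0) -> ImageVolume:
    """Z-score normalisation over foreground voxels.

    Foreground is every voxel strictly above the ``floor_percentile`` of
    the intensity distribution; after normalisation that set has mean 0
    and standard deviation 1.  Constant images have no spread to
    normalise and raise.
    """
    floor = np.percentile(image.values, floor_percentile)
    foreground = image.values > floor
    if not foreground.any() or np.ptp(image.values) == 0:
        raise ValidationError("cannot z-score a constant image")
    mu = image.values[foreground].mean()
    sigma = image.values[foreground].std()
    if sigma == 0:
        raise ValidationError("foreground intensities are constant; cannot z-score")
    return image.with_values((image.values - mu) / sigma)


def ensemble_vote(masks: list[BinaryMask]) -> BinaryMask:
    """Majority vote over predicted masks from multiple prior sessions.

    A voxel is foreground when at least half the sources mark it (ties go
    to foreground).
    """
    if not masks:
        raise ValidationError("ensemble_vote needs at least one mask")
    first = masks[0]
    for other in masks[1:]:
        first.require_same_geometry(other, "ensemble masks")
    votes = np.sum([m.voxels for m in masks], axis=0)
    return BinaryMask(voxels=2 * votes >= len(masks),
                      spacing_mm=first.spacing_mm, origin_mm=first.origin_mm)


# ---------------------------------------------------------------------------
# dataset layout
# ---------------------------------------------------------------------------

def write_dataset(
    cases: list[ConditionedCase],
    registry: CohortRegistry,
    output_root: str | Path,
    split: FoldSplit | None = None,
    *,
    normalize: bool = False,
) -> pd.DataFrame:
    """Write a raw three-channel dataset layout and return its manifest.

    Layout: ``imagesTr/<case>_0000|_0001|_0002.nii.gz`` (source image,
    source organ mask, target image), ``labelsTr/<case>.nii.gz`` (binary
    target), ``dataset.json`` descriptor, and ``manifest.csv`` mapping
    case ids to (patient, m, n, organ, fold).  The layout round-trips via
    :func:`read_dataset`.
    """
    root = Path(output_root)
    images_dir = root / "imagesTr"
    labels_dir = root / "labelsTr"
    images_dir.mkdir(parents=True, exist_ok=True)
    labels_dir.mkdir(parents=True, exist_ok=True)

    ids = [case.case_id for case in cases]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"case id collisions: {dupes}")

    fold_of = {}
    if split is not None:
        for pid in split.train_patients:
            fold_of[pid] = f"fold{split.fold_id}_train"
        fold_of[split.validation_patient] = f"fold{split.fold_id}_validation"
        for pid in split.test_patients:
            fold_of[pid] = "test"

    rows = []
    for case in cases:
        full = materialize_case(case, registry, normalize=normalize)
        for channel_idx, channel in enumerate((full.channel_0, full.channel_1, full.channel_2)):
            channel.save(images_dir / f"{case.case_id}_{channel_idx:04d}.nii.gz")
        if full.target_label is None:
            raise ConfigurationError(f"case {case.case_id}: no target labels in registry")
        full.target_label.save(labels_dir / f"{case.case_id}.nii.gz")
        rows.append({
            "case_id": case.case_id,
            "patient_id": case.patient_id,
            "source_session": case.source_session,
            "target_session": case.target_session,
            "organ": case.organ,
            "organ_code": case.organ_code,
            "fold": fold_of.get(case.patient_id, ""),
        })

    manifest = pd.DataFrame(rows).sort_values("case_id").reset_index(drop=True)
    manifest.to_csv(root / "manifest.csv", index=False)
    descriptor = {
        "channel_names": {str(i): name for i, name in enumerate(CHANNEL_NAMES)},
        "labels": {"background": 0, "organ": 1},
        "file_ending": ".nii.gz",
        "numTraining": len(cases),
    }
    (root / "dataset.json").write_text(json.dumps(descriptor, indent=2, sort_keys=True))
    return manifest


def read_dataset(output_root: str | Path) -> list[ConditionedCase]:
    """Reconstruct every conditioned case (metadata + voxel data) from disk."""
    root = Path(output_root)
    manifest = pd.read_csv(root / "manifest.csv", keep_default_na=False)
    cases = []
    for row in manifest.itertuples(index=False):
        channels = [ImageVolume.load(root / "imagesTr" / f"{row.case_id}_{i:04d}.nii.gz")
                    for i in range(3)]
        target = BinaryMask.load(root / "labelsTr" / f"{row.case_id}.nii.gz")
        cases.append(ConditionedCase(
            patient_id=str(row.patient_id),
            source_session=int(row.source_session),
            target_session=int(row.target_session),
            organ=str(row.organ),
            organ_code=int(row.organ_code),
            channel_0=channels[0], channel_1=channels[1], channel_2=channels[2],
            target_label=target,
        ))
    return cases
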