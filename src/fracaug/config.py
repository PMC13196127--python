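"""YAML run configuration with fail-fast schema checking.

A run config is a YAML mapping with a ``schema_version`` and optional
blocks ``phantom``, ``deform``, and ``mr_augmentations`` whose keys map
one-to-one onto the corresponding dataclass fields.  Unknown keys are
rejected rather than ignored, and every run writes a resolved snapshot of
the config it actually used next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .deform import DeformParams
from .errors import ConfigurationError
from .mraug import MrAugConfig
from .phantom import IntensityModel, PhantomSpec

SCHEMA_VERSION = 1

_TOP_LEVEL_KEYS = {"schema_version", "seed", "phantom", "deform", "mr_augmentations"}


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    deform: DeformParams = field(default_factory=DeformParams)
    mr_augmentations: MrAugConfig | None = None


def _build(cls, block: dict, context: str):
    if not isinstance(block, dict):
        raise ConfigurationError(f"config block {context!r} must be a mapping")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(f"unknown keys in {context!r}: {sorted(unknown)}")
    kwargs = dict(block)
    for key in ("grid_shape", "spacing_mm", "organ_set", "intensity_scale_range",
                "gibbs_alpha_range"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    if cls is PhantomSpec and isinstance(kwargs.get("intensity_model"), dict):
        kwargs["intensity_model"] = _build(IntensityModel, kwargs["intensity_model"],
                                           f"{context}.intensity_model")
    return cls(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("run config must be a YAML mapping")
    unknown = set(raw) - _TOP_LEVEL_KEYS
    if unknown:
        raise ConfigurationError(f"unknown top-level config keys: {sorted(unknown)}")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigurationError(f"unsupported config schema_version {version}")
    seed = int(raw.get("seed", 0))
    phantom = _build(PhantomSpec, raw.get("phantom", {}), "phantom")
    if "seed" not in raw.get("phantom", {}):
        phantom = dataclasses.replace(phantom, seed=seed)
    deform = _build(DeformParams, raw.get("deform", {}), "deform")
    mraug = None
    if "mr_augmentations" in raw:
        mraug = _build(MrAugConfig, raw["mr_augmentations"], "mr_augmentations")
    return RunConfig(seed=seed, phantom=phantom, deform=deform, mr_augmentations=mraug)


def snapshot_config(config: RunConfig, out_dir: str | Path) -> Path:
    """Write the resolved config next to a run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "resolved_config.json"
    path.write_text(json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True,
                               default=str))
    return path
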