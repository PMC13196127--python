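"""Deterministic per-stage seed derivation.

Every pipeline stage derives its own child seed from the single root seed
and a stage label, so stages can be rerun independently while the whole
run stays reproducible from one integer.
"""

from __future__ import annotations

import hashlib

import numpy as np


def child_seed(root_seed: int, stage: str) -> int:
    """A stable 31-bit child seed for ``stage`` under ``root_seed``."""
    digest = hashlib.sha256(f"{int(root_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def stage_rng(root_seed: int, stage: str) -> np.random.Generator:
    """Generator seeded with :func:`child_seed`."""
    return np.random.default_rng(child_seed(root_seed, stage))
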