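"""Small shared helpers: seed derivation and validation."""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "check_finite"]


def derive_seed(master_seed: int, *tags: object) -> int:
    """Derive a deterministic child seed < 2**31 from a master seed and tags.

    Hash-based so that adding a subject or stage never shifts the seeds of
    the others.
    """
    key = ":".join([str(int(master_seed))] + [str(t) for t in tags])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
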