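"""Named-stream random number generation.

Every source of randomness in the package flows from one root integer seed
through :func:`stream`, which derives an independent ``numpy`` Generator from
the root seed plus a tuple of string/int labels (e.g. ``("subject", "S03",
"site", "thigh")``).  The derivation is a SHA-256 hash, so it is stable across
processes, platforms and numpy versions, and any single artifact can be
regenerated in isolation without replaying the whole cohort.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stream", "substream_seed"]


def substream_seed(root_seed: int, *labels: object) -> int:
    """Derive a deterministic 31-bit seed from a root seed and labels."""
    h = hashlib.sha256()
    h.update(str(int(root_seed)).encode())
    for lab in labels:
        h.update(b"\x00")
        h.update(str(lab).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def stream(root_seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator for the named substream of ``root_seed``."""
    return np.random.default_rng(substream_seed(root_seed, *labels))
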