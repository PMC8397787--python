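"""Deterministic seed derivation.

Every stochastic operation in the package takes an integer seed. Pipelines
derive per-operation seeds from one global seed plus a stable string tag so
that a single ``--seed`` reproduces an entire run end-to-end.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]

_MOD = 2**31 - 1


def derive_seed(global_seed: int, tag: str) -> int:
    """Derive a child seed from ``global_seed`` and a stable operation tag.

    The mapping is a fixed hash, independent of Python's randomized
    ``hash()``; results are always in ``[0, 2**31 - 1)``.
    """
    digest = hashlib.sha256(f"{int(global_seed)}:{tag}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % _MOD
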