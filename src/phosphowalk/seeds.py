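"""Stable seed derivation.

One global seed fans out to per-stage seeds by hashing the seed together with
a stage tag, so each stage is individually reproducible and stages are not
coupled through a shared stream.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(seed: int, *tags: object) -> int:
    """A deterministic 31-bit seed for the stage named by ``tags``."""
    text = "|".join([str(int(seed)), *map(str, tags)])
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
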