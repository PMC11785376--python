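"""Deterministic per-stage seed derivation.

Every stochastic stage draws from its own seed derived from the master seed
and a stage label, so inserting or reordering stages never shifts another
stage's randomness.  Derived seeds stay below 2**31.
"""

from __future__ import annotations

import hashlib


def derive_seed(master: int, stage: str) -> int:
    digest = hashlib.blake2s(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF
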