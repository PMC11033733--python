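"""Deterministic seed derivation shared across pipeline stages."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(*parts) -> int:
    """Stable 32-bit seed from arbitrary string-able parts.

    Hash-based so serial and parallel stage execution agree on per-stage,
    per-stratum seeds.
    """
    key = ":".join(str(p) for p in parts).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "little")


def generator(*parts) -> np.random.Generator:
    return np.random.default_rng(derive_seed(*parts))
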