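"""Seed derivation and digest helpers.

All stochastic components draw from numpy Generators whose seeds are derived
from one master seed by stable hashing of string tokens, so that every
artifact is reproducible independently of generation order.
"""

from __future__ import annotations

import hashlib
import json
from typing import Any

import numpy as np

_SEED_MOD = 2**31


def derive_seed(master: int, *tokens: Any) -> int:
    """Derive a sub-seed (< 2**31) from a master seed and string tokens."""
    payload = repr((int(master),) + tuple(str(t) for t in tokens)).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "big") % _SEED_MOD


def rng_for(master: int, *tokens: Any) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, *tokens))


def stable_digest(obj: Any) -> str:
    """Short hex digest of a JSON-serializable object, for provenance headers."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
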