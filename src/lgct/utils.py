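"""Small shared utilities."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(root_seed: int, name: str) -> int:
    """Deterministic per-module seed from a single root seed.

    Stable across platforms and sessions (blake2b of "root:name", first
    4 bytes, folded below 2**31).
    """
    digest = hashlib.blake2b(f"{root_seed}:{name}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2**31)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out
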