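"""Trials-bundle format: a directory with ``manifest.json`` plus a flat
``data.bin`` (little-endian float, trial-major, channel-then-sample order).

The round trip write -> read is bit-exact in the stored dtype (float32 by
default; float64 supported via the manifest ``dtype`` field).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .data import EpochSet, Montage

__all__ = ["read_trials_bundle", "write_trials_bundle", "BundleError"]

SCHEMA_VERSION = 1
_DTYPES = {"float32": "<f4", "float64": "<f8"}


class BundleError(ValueError):
    pass


def write_trials_bundle(epochs: EpochSet, path, dtype: str | None = None) -> None:
    """dtype None keeps the array's own precision."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if dtype is None:
        dtype = str(epochs.data.dtype)
    if dtype not in _DTYPES:
        raise BundleError(f"unsupported dtype {dtype!r}")
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "fs": epochs.fs,
        "channel_names": list(epochs.montage.channel_names),
        "labels": [int(x) for x in epochs.labels],
        "sessions": [int(x) for x in epochs.sessions],
        "n_trials": epochs.n_trials,
        "n_channels": epochs.n_channels,
        "n_samples": epochs.n_samples,
        "dtype": dtype,
    }
    (path / "manifest.json").write_text(json.dumps(manifest))
    arr = np.ascontiguousarray(epochs.data, dtype=_DTYPES[dtype])
    (path / "data.bin").write_bytes(arr.tobytes())


def read_trials_bundle(path) -> EpochSet:
    path = Path(path)
    try:
        manifest = json.loads((path / "manifest.json").read_text())
    except FileNotFoundError:
        raise BundleError(f"no manifest.json under {path}") from None
    version = manifest.get("schema_version")
    if version != SCHEMA_VERSION:
        raise BundleError(f"unsupported schema version {version!r}")
    dtype = manifest.get("dtype", "float32")
    if dtype not in _DTYPES:
        raise BundleError(f"unsupported dtype {dtype!r} in manifest")
    n, c, s = (int(manifest[k]) for k in ("n_trials", "n_channels", "n_samples"))
    names = manifest["channel_names"]
    if len(names) != c:
        raise BundleError(
            f"manifest lists {len(names)} channel names for {c} channels")
    raw = (path / "data.bin").read_bytes()
    itemsize = np.dtype(_DTYPES[dtype]).itemsize
    expected = n * c * s * itemsize
    if len(raw) != expected:
        raise BundleError(
            f"data.bin holds {len(raw)} bytes, manifest implies {expected} "
            "(truncated or inconsistent)")
    data = np.frombuffer(raw, dtype=_DTYPES[dtype]).reshape(n, c, s).copy()
    return EpochSet(data, float(manifest["fs"]),
                    np.array(manifest["labels"], dtype=int),
                    np.array(manifest["sessions"], dtype=int),
                    Montage.from_labels(names))
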