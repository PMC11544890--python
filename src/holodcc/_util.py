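"""Small shared helpers: seed derivation, hashing, truncated-normal draws."""

from __future__ import annotations

import hashlib
import json
import zlib
from typing import Any

import numpy as np

_MOD = 2**31


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: mixes the run seed with a CRC of the stage name."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % _MOD


def truncated_normal(rng: np.random.Generator, clip: float = 2.5) -> float:
    """Standard-normal draw clipped to ±clip (keeps sampled morphology bounded)."""
    return float(np.clip(rng.standard_normal(), -clip, clip))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def stable_json(obj: Any) -> str:
    """Deterministic JSON rendering (sorted keys, no whitespace drift)."""
    return json.dumps(obj, sort_keys=True, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
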