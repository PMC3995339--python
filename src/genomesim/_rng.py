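"""Seed-substream discipline.

A single root seed deterministically spawns one independent generator per
(replicate, region, purpose). Streams are keyed structurally rather than drawn
sequentially, so adding a region or replicate never perturbs the draws of any
other stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key: int | str) -> int:
    if isinstance(key, (int, np.integer)):
        if key < 0:
            raise ValueError(f"substream keys must be nonnegative, got {key}")
        return int(key)
    return zlib.crc32(str(key).encode("utf-8"))


def substream(seed: int, *keys: int | str) -> np.random.Generator:
    """Return an independent Generator for ``(seed, *keys)``.

    String keys (stream purposes such as ``"genealogy"``) are mapped to
    integers with CRC-32; integer keys (replicate/region indices) are used
    directly as part of the SeedSequence spawn key.
    """
    spawn_key = tuple(_key_to_int(k) for k in keys)
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=spawn_key)
    return np.random.default_rng(ss)
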