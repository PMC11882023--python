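"""Small shared helpers: half-up rounding and seed streams."""

from __future__ import annotations

import math
import zlib

import numpy as np


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero on the positive axis (0.5 -> 1).

    Python's built-in ``round`` is banker's rounding; reported counts and
    percentages here follow the half-up convention of the source tables.
    """
    scale = 10.0**ndigits
    r = math.floor(x * scale + 0.5) / scale
    return int(r) if ndigits <= 0 else r


def derive_rng(seed: int, *stream: str | int) -> np.random.Generator:
    """Independent generator for a named sub-stream of a global seed.

    Each pipeline stage draws from its own stream so stages can be
    regenerated independently without perturbing one another.
    """
    # crc32, not hash(): the latter is salted per process and would break
    # cross-run determinism of seeded output.
    key = tuple(
        zlib.crc32(str(s).encode("utf-8")) & 0x7FFFFFFF for s in stream
    )
    ss = np.random.SeedSequence(seed, spawn_key=key)
    return np.random.default_rng(ss)
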