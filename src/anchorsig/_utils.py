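"""Small shared helpers: symbol normalization and seeded random substreams."""

from __future__ import annotations

import zlib
from typing import Iterable

import numpy as np


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: stripped of surrounding whitespace, uppercased."""
    return str(symbol).strip().upper()


def normalize_symbols(symbols: Iterable[str]) -> set[str]:
    """Normalize a collection of symbols into a set, dropping empty strings."""
    out = {normalize_symbol(s) for s in symbols}
    out.discard("")
    return out


def substream(seed: int, *tags) -> np.random.Generator:
    """Derive an independent, reproducible RNG from a root seed and a key path.

    Every source of randomness in the package draws from a generator created
    here, so a single integer seed plus a stable tag sequence (strings are
    hashed with CRC32, integers used directly) fully determines all output.
    """
    words = [int(seed) & 0x7FFFFFFF]
    for tag in tags:
        if isinstance(tag, str):
            words.append(zlib.crc32(tag.encode("utf-8")))
        else:
            words.append(int(tag) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(words))
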