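"""Shared plumbing: errors and labelled pseudo-random streams."""

from __future__ import annotations

import zlib

import numpy as np


class ConfigError(ValueError):
    """An invalid simulation or analysis configuration."""


class ValidationError(ValueError):
    """Input data violating a documented invariant."""


def stream(seed: int, *labels: object) -> np.random.Generator:
    """Return a PRNG stream derived from ``seed`` and stable string labels.

    Each generated object gets its own stream keyed by (seed, labels), so
    adding a mouse or a feature never shifts the draws of any other object.
    """
    words = [int(seed) & 0x7FFFFFFF]
    words.extend(zlib.crc32(str(lab).encode()) for lab in labels)
    return np.random.default_rng(words)
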