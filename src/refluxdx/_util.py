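from __future__ import annotations

import math

import numpy as np


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (table convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def check_finite(name: str, value: float) -> float:
    if not math.isfinite(value):
        raise_validation(name, value, "must be finite")
    return float(value)


def raise_validation(name: str, value, constraint: str):
    from .errors import ValidationError

    raise ValidationError(f"{name}={value!r}: {constraint}")


def sub_rng(seed: int, *stream: int) -> np.random.Generator:
    # named sub-generator: one master seed, one spawn key per patient/label
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])
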