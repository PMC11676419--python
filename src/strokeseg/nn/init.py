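"""Weight initialisation.

He-normal draws for ReLU networks: weights come from a zero-mean normal with
sigma = sqrt(2 / m), where m is the fan-in of the weight tensor, truncated at
+/- 2 sigma.  The truncation is sampled exactly through the inverse normal
CDF, so a fixed generator state reproduces draws bit-for-bit.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = ["he_sigma", "truncated_normal", "he_normal"]

_TRUNC = 2.0


def he_sigma(fan_in: int) -> float:
    """sigma = sqrt(2/m) for fan-in m."""
    if fan_in < 1:
        raise ValueError(f"fan_in must be >= 1, got {fan_in}")
    return math.sqrt(2.0 / fan_in)


def truncated_normal(shape, sigma: float, rng: np.random.Generator,
                     trunc: float = _TRUNC) -> np.ndarray:
    """Zero-mean normal(sigma) truncated at ``+/- trunc * sigma``."""
    lo = ndtr(-trunc)
    hi = ndtr(trunc)
    u = rng.random(shape)
    return (sigma * ndtri(lo + u * (hi - lo))).astype(np.float64)


def he_normal(shape, fan_in: int, rng: np.random.Generator) -> np.ndarray:
    """He-normal truncated draws for a weight tensor of ``shape``."""
    return truncated_normal(shape, he_sigma(fan_in), rng)
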