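"""Reproducible truncated-normal sampling.

All stochastic primitives in the simulator draw from normal distributions
truncated to [0, 1] (belief priors, misinformation cues, cue-detection
thresholds, baseline sensitivities).  Draws are produced by inverse-CDF
transform of uniforms from a ``numpy.random.Generator``: for a fixed seed
and draw order the output is bit-reproducible, and a single uniform is
consumed per variate regardless of the truncation bounds.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = ["truncated_normal"]


def truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    low: float = 0.0,
    high: float = 1.0,
    size: int | None = None,
):
    """Draw from a normal(mean, sd) truncated to [low, high].

    Parameters
    ----------
    rng
        Source of uniforms; exactly one uniform is consumed per variate.
    mean, sd
        Parameters of the parent (untruncated) normal. ``sd == 0`` is the
        degenerate limit: every draw equals ``mean`` (clipped to the bounds).
    low, high
        Truncation bounds, ``low < high``.
    size
        ``None`` returns a scalar float, otherwise an array of that length.

    Returns
    -------
    float or numpy.ndarray
        Variate(s) in [low, high].
    """
    if high <= low:
        raise ValueError(f"empty truncation interval [{low}, {high}]")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        value = min(max(mean, low), high)
        return value if size is None else np.full(size, value)
    u = rng.random(size)
    a = ndtr((low - mean) / sd)
    b = ndtr((high - mean) / sd)
    x = mean + sd * ndtri(a + u * (b - a))
    # inverse-CDF can land exactly on a bound at the float limits
    return float(np.clip(x, low, high)) if size is None else np.clip(x, low, high)
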