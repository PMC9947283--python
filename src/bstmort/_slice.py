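"""Univariate slice sampler (stepping out + shrinkage)."""

from __future__ import annotations

from typing import Callable

import numpy as np


def slice_sample(logpdf: Callable[[float], float], x0: float,
                 rng: np.random.Generator, w: float = 1.0, max_steps: int = 50,
                 lo: float = -np.inf, hi: float = np.inf) -> float:
    """One slice-sampling update of a univariate log density.

    ``lo``/``hi`` optionally bound the support (the interval is clipped to
    them).  Returns the new point; the update leaves ``exp(logpdf)``
    invariant.
    """
    f0 = logpdf(x0)
    if not np.isfinite(f0):
        raise ValueError("slice_sample started at a point of zero density")
    level = f0 + np.log(rng.uniform())
    left = x0 - w * rng.uniform()
    right = left + w
    j = int(np.floor(max_steps * rng.uniform()))
    k = max_steps - 1 - j
    while j > 0 and left > lo and logpdf(max(left, lo)) > level:
        left -= w
        j -= 1
    while k > 0 and right < hi and logpdf(min(right, hi)) > level:
        right += w
        k -= 1
    left = max(left, lo)
    right = min(right, hi)
    while True:
        x1 = left + (right - left) * rng.uniform()
        if logpdf(x1) > level:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
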