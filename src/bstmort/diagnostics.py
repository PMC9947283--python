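"""MCMC convergence assessment via the Brooks-Gelman-Rubin ratio.

The implemented statistic is the classic Gelman-Rubin potential scale
reduction factor with the (m+1)/(m*n) between-chain term and without the
Brooks-Gelman degrees-of-freedom correction; chains are used whole
(post burn-in), with no split-chain variant.  Values near 1 indicate
convergence; the operative rule is the share of parameters above a
threshold (1.05 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ConvergenceReport:
    ratios: dict[str, float]
    fraction_above_threshold: float
    threshold: float


def bgr_ratio(chains) -> float:
    """Brooks-Gelman-Rubin ratio for m chains of n draws each.

    With chain means t_j, grand mean t, B = n/(m-1) * sum_j (t_j - t)^2,
    W = mean of the unbiased within-chain variances, and
    Vhat = (n-1)/n * W + (m+1)/(m*n) * B, returns sqrt(Vhat / W).
    """
    if not isinstance(chains, np.ndarray):
        lengths = {len(c) for c in chains}
        if len(lengths) > 1:
            raise ValueError(f"chains have unequal lengths: {sorted(lengths)}")
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a chains x draws array")
    m, n = x.shape
    if m < 2:
        raise ValueError("at least two chains are required")
    if n < 2:
        raise ValueError("chains must have at least two draws")
    chain_means = x.mean(axis=1)
    B = n / (m - 1) * np.sum((chain_means - chain_means.mean()) ** 2)
    W = x.var(axis=1, ddof=1).mean()
    if W == 0:
        raise ValueError("constant chains: within-chain variance is zero")
    vhat = (n - 1) / n * W + (m + 1) / (m * n) * B
    return float(np.sqrt(vhat / W))


def convergence_report(samples, threshold: float = 1.05) -> ConvergenceReport:
    """Per-parameter BGR ratios and the fraction above ``threshold``.

    ``samples`` is a PosteriorSamples object (or anything exposing
    ``parameter_dict()`` mapping scalar-parameter names to chains x draws
    arrays).  Parameters whose draws are exactly constant across all
    chains (e.g. structured effects of island countries, pinned at 0)
    carry no convergence information and are skipped.
    """
    params = samples.parameter_dict()
    ratios: dict[str, float] = {}
    for name, arr in params.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"parameter {name}: expected chains x draws array")
        if arr.shape[0] < 2:
            raise ValueError("at least two chains are required")
        if np.ptp(arr) == 0:
            continue
        ratios[name] = bgr_ratio(arr)
    if not ratios:
        raise ValueError("no non-constant parameters to diagnose")
    frac = float(np.mean([r > threshold for r in ratios.values()]))
    return ConvergenceReport(ratios=ratios, fraction_above_threshold=frac,
                             threshold=threshold)
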