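"""Interpretive outputs: annual percent change, trend classes, overall curve.

The fitted model decomposes each country's log-mortality trajectory into
a stable spatial departure s_i, a global linear trend b0, a common
nonlinear wiggle v_t and a country-specific slope departure b1i.  This
module turns posterior summaries of those pieces into the quantities a
reader acts on: percent decline per year, a per-country trend class, and
the overall temporal trend curve with its credible band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TREND_CLASSES = (
    "rising",
    "declining_faster_than_global",
    "declining_slower_than_global",
    "declining_at_global_rate",
)


@dataclass
class TrendSummary:
    """Posterior-median decomposition of mortality trends.

    Per-country medians of s_i, b1i and b0+b1i (medians of per-draw sums,
    never sums of medians), the global b0 median, and the v_t trajectory
    with central 95% intervals.
    """

    countries: list[str]
    s_i_median: np.ndarray
    b1i_median: np.ndarray
    b0_plus_b1i_median: np.ndarray
    trend_class: list[str]
    b0_median: float
    years: list[int]
    v_median: np.ndarray
    v_lower95: np.ndarray
    v_upper95: np.ndarray
    indicator: str = "NMR"
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "country_id": self.countries,
            "s_i_median": self.s_i_median,
            "b1i_median": self.b1i_median,
            "b0_plus_b1i_median": self.b0_plus_b1i_median,
            "trend_class": self.trend_class,
        })


def annual_percent_change(b: float) -> float:
    """Percent decline per year implied by a log-scale slope ``b``.

    Returns 100*(1 - exp(b)): positive for a declining rate.  Rounding to
    two decimals is left to presentation code; the raw value is returned.
    """
    return 100.0 * (1.0 - np.exp(b))


def classify_trend(b0_median: float, b1i_median: float, tol: float = 1e-6) -> str:
    """Assign a country's trend class from posterior medians.

    A country's own slope is b0 + b1i; it is "rising" when that sum is
    positive.  Otherwise the sign of b1i says whether it declines faster
    or slower than the global rate, with a tolerance band around 0.
    """
    if b0_median + b1i_median > 0:
        return "rising"
    if b1i_median < -tol:
        return "declining_faster_than_global"
    if b1i_median > tol:
        return "declining_slower_than_global"
    return "declining_at_global_rate"


def overall_trend_curve(samples) -> pd.DataFrame:
    """Per-year median and central 95% interval of b0*t~ + v_t.

    ``samples`` is a PosteriorSamples object; chains are pooled and the
    quantity is computed per draw before taking quantiles.
    """
    b0 = samples.b0.reshape(-1)
    if b0.size == 0:
        raise ValueError("empty posterior samples")
    v = samples.v.reshape(-1, samples.v.shape[-1])
    years = np.asarray(samples.years, dtype=float)
    tt = years - years.mean()
    curve = b0[:, None] * tt[None, :] + v  # draws x years
    qs = np.quantile(curve, [0.025, 0.5, 0.975], axis=0)
    return pd.DataFrame({
        "year": [int(y) for y in samples.years],
        "median": qs[1],
        "lower95": qs[0],
        "upper95": qs[2],
    })
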