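"""Distribution-pattern analyses of cross-country mortality rates.

Kernel density estimation with the Epanechnikov kernel, coefficient-of-
variation trajectories across years, per-year five-number summaries and
regional mean-rate trends.  These work on the raw rates (per 1,000 live
births), not the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import MortalityPanel


@dataclass
class KdeCurve:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int


@dataclass
class DispersionSeries:
    years: list[int]
    cv: np.ndarray
    indicator: str


def epanechnikov_kernel(u):
    """K(u) = 0.75*(1 - u^2) on [-1, 1], 0 outside."""
    u = np.asarray(u, dtype=float)
    out = 0.75 * (1.0 - u ** 2) * (np.abs(u) <= 1.0)
    return float(out) if out.ndim == 0 else out


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    sd = values.std(ddof=1) if n > 1 else 0.0
    iqr = float(np.subtract(*np.quantile(values, [0.75, 0.25])))
    spread = min(sd, iqr / 1.34) if min(sd, iqr) > 0 else max(sd, iqr / 1.34)
    if spread <= 0:
        raise ValueError("cannot choose a bandwidth for degenerate data")
    return 0.9 * spread * n ** (-0.2)


def kde(values, grid=None, h: float | None = None) -> KdeCurve:
    """Normalised kernel density estimate with the Epanechnikov kernel.

    density(g) = (1/(n*h)) * sum_i K((x_i - g)/h).  The bandwidth
    defaults to Silverman's rule; the grid defaults to 512 points
    spanning the data support extended by one bandwidth.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("kde requires at least one value")
    if h is None:
        h = silverman_bandwidth(values)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        grid = np.linspace(values.min() - h, values.max() + h, 512)
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    dens = epanechnikov_kernel((values[None, :] - grid[:, None]) / h).sum(axis=1)
    dens /= len(values) * h
    return KdeCurve(grid=grid, density=dens, bandwidth=float(h), n=len(values))


def coefficient_of_variation(values) -> float:
    """Population standard deviation divided by the mean."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("coefficient_of_variation requires values")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("coefficient of variation requires a positive mean")
    return float(values.std(ddof=0) / mean)


def dispersion_series(panel: MortalityPanel) -> DispersionSeries:
    """Per-year CV of the raw rates across countries."""
    rates = panel.rate_matrix()
    cv = np.array([coefficient_of_variation(rates[:, j])
                   for j in range(rates.shape[1])])
    return DispersionSeries(years=panel.years, cv=cv, indicator=panel.indicator)


def region_trends(panel: MortalityPanel, regions: dict[str, str]) -> pd.DataFrame:
    """Unweighted mean rate per region and year, plus a "World" column.

    The World column is the mean over all countries regardless of the
    region partition; countries mapped to "unassigned" (or not mapped)
    contribute to World only.  Regions with no countries are absent.
    """
    df = panel.data.copy()
    df["region"] = df["country"].map(regions).fillna("unassigned")
    wide = (df[df["region"] != "unassigned"]
            .groupby(["year", "region"])["rate"].mean().unstack())
    world = df.groupby("year")["rate"].mean()
    wide = wide if wide is not None else pd.DataFrame(index=world.index)
    wide["World"] = world
    wide.index = wide.index.astype(int)
    return wide


def boxplot_summary(panel: MortalityPanel) -> pd.DataFrame:
    """Per-year five-number summary (min, Q1, median, Q3, max) of rates.

    Quantiles use linear interpolation of the empirical CDF.
    """
    rates = panel.rate_matrix()
    qs = np.quantile(rates, [0.0, 0.25, 0.5, 0.75, 1.0], axis=0)
    return pd.DataFrame({"year": panel.years, "min": qs[0], "q1": qs[1],
                         "median": qs[2], "q3": qs[3], "max": qs[4]})
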