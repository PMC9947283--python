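"""Reading, validating and writing long-format mortality panels.

A panel is a long table of country-year-indicator mortality rates
(deaths per 1,000 live births).  The model downstream works on the
natural log of the rates, so zero or negative rates are rejected at
the door.  Countries with any missing year for the analysed indicator
are dropped entirely (listwise deletion) so that every retained
country contributes a complete trajectory.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .reporting import TrendSummary

logger = logging.getLogger(__name__)

INDICATORS = ("NMR", "IMR", "CMR")

#: The seven UNICEF world regions used for regional aggregation.
UNICEF_REGIONS = (
    "East Asia and Pacific",
    "Europe and Central Asia",
    "Latin America and the Caribbean",
    "Middle East and North Africa",
    "North America",
    "South Asia",
    "Sub-Saharan Africa",
)

_PANEL_COLUMNS = ["country", "year", "indicator", "rate"]


@dataclass(frozen=True)
class PanelRecord:
    """One country-year-indicator observation."""

    country_id: str
    year: int
    indicator: str
    rate: float


@dataclass
class MortalityPanel:
    """Complete rectangular panel of one indicator's rates.

    ``data`` holds the long table restricted to a single indicator;
    ``countries`` and ``years`` fix the row/column order of the rate
    matrix.  ``complete`` is True when every (country, year) pair has
    exactly one record.
    """

    data: pd.DataFrame
    indicator: str
    complete: bool = False
    excluded_countries: list[str] = field(default_factory=list)

    @property
    def countries(self) -> list[str]:
        return sorted(self.data["country"].unique().tolist())

    @property
    def years(self) -> list[int]:
        return sorted(int(y) for y in self.data["year"].unique())

    @property
    def records(self) -> list[PanelRecord]:
        return [
            PanelRecord(r.country, int(r.year), r.indicator, float(r.rate))
            for r in self.data.itertuples(index=False)
        ]

    def rate_matrix(self) -> np.ndarray:
        """Countries x years matrix of raw rates (panel order)."""
        if not self.complete:
            raise ValueError("rate_matrix requires a complete panel")
        wide = self.data.pivot(index="country", columns="year", values="rate")
        wide = wide.loc[self.countries, self.years]
        return wide.to_numpy(dtype=float)


def _atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write text to ``path`` atomically (temp file + rename)."""
    path = os.fspath(path)
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp_", text=True)
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_panel(path: str | os.PathLike, indicator: str) -> MortalityPanel:
    """Read a long-format panel CSV and restrict it to one indicator.

    The file must have header ``country,year,indicator,rate``.  Countries
    missing any year for the requested indicator are dropped (listwise
    deletion) and logged; the returned panel is complete by construction.

    Raises
    ------
    ValueError
        On malformed rows (with the 1-based line number), non-positive
        rates, duplicate records, or an empty result after filtering.
    """
    if indicator not in INDICATORS:
        raise ValueError(f"unknown indicator {indicator!r}; expected one of {INDICATORS}")
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != _PANEL_COLUMNS:
        raise ValueError(
            f"panel file must have header {','.join(_PANEL_COLUMNS)}; got {list(df.columns)}"
        )
    # +2: 1-based line numbers, header on line 1
    for col, kind in (("year", int), ("rate", float)):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna()]
        if len(bad):
            raise ValueError(f"malformed {col!r} value on line {bad[0] + 2}: {df.loc[bad[0], col]!r}")
        df[col] = converted.astype(kind)
    nonpos = df.index[df["rate"] <= 0]
    if len(nonpos):
        i = nonpos[0]
        raise ValueError(
            f"non-positive rate on line {i + 2} "
            f"(country {df.loc[i, 'country']}, year {int(df.loc[i, 'year'])}): log-rates are modelled"
        )
    bad_ind = df.index[~df["indicator"].isin(INDICATORS)]
    if len(bad_ind):
        raise ValueError(
            f"unknown indicator on line {bad_ind[0] + 2}: {df.loc[bad_ind[0], 'indicator']!r}"
        )
    sub = df[df["indicator"] == indicator].copy()
    dup = sub.duplicated(subset=["country", "year"])
    if dup.any():
        i = sub.index[dup][0]
        raise ValueError(
            f"duplicate record on line {i + 2} "
            f"(country {sub.loc[i, 'country']}, year {int(sub.loc[i, 'year'])})"
        )
    if sub.empty:
        raise ValueError(f"no records for indicator {indicator!r}")

    years = sorted(int(y) for y in sub["year"].unique())
    counts = sub.groupby("country")["year"].count()
    kept = counts.index[counts == len(years)].tolist()
    excluded = sorted(set(sub["country"]) - set(kept))
    if excluded:
        logger.warning(
            "listwise deletion dropped %d countries with incomplete %s series: %s",
            len(excluded), indicator, ", ".join(excluded),
        )
    sub = sub[sub["country"].isin(kept)]
    if sub.empty:
        raise ValueError(f"no complete countries remain for indicator {indicator!r}")
    sub = sub.sort_values(["country", "year"]).reset_index(drop=True)
    return MortalityPanel(data=sub, indicator=indicator, complete=True,
                          excluded_countries=excluded)


def panel_from_matrix(rates: np.ndarray, countries: Sequence[str],
                      years: Sequence[int], indicator: str = "NMR") -> MortalityPanel:
    """Build a complete panel from a countries x years rate matrix."""
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (len(countries), len(years)):
        raise ValueError("rate matrix shape does not match countries x years")
    if np.any(rates <= 0):
        raise ValueError("all rates must be positive")
    order = np.argsort(np.asarray(countries, dtype=object))
    recs = []
    for i in order:
        for j, yr in enumerate(years):
            recs.append((countries[i], int(yr), indicator, float(rates[i, j])))
    df = pd.DataFrame(recs, columns=_PANEL_COLUMNS)
    return MortalityPanel(data=df, indicator=indicator, complete=True)


def write_panel(panel: MortalityPanel, path: str | os.PathLike) -> None:
    """Write a panel back to CSV (header ``country,year,indicator,rate``)."""
    df = panel.data[_PANEL_COLUMNS].copy()
    lines = [",".join(_PANEL_COLUMNS)]
    for r in df.itertuples(index=False):
        lines.append(f"{r.country},{int(r.year)},{r.indicator},{float(r.rate)!r}")
    _atomic_write_text(path, "\n".join(lines) + "\n")


def log_matrix(panel: MortalityPanel) -> np.ndarray:
    """Countries x years matrix of natural-log rates.

    Row order follows ``panel.countries``, column order ``panel.years``.
    """
    if not panel.complete:
        raise ValueError("log_matrix requires a complete panel")
    return np.log(panel.rate_matrix())


def read_region_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a ``country,region`` CSV into a country -> region mapping.

    Regions must come from the seven UNICEF region names or be
    ``"unassigned"``.
    """
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != ["country", "region"]:
        raise ValueError("region map must have header country,region")
    allowed = set(UNICEF_REGIONS) | {"unassigned"}
    bad = df.index[~df["region"].isin(allowed)]
    if len(bad):
        raise ValueError(f"unknown region on line {bad[0] + 2}: {df.loc[bad[0], 'region']!r}")
    return dict(zip(df["country"], df["region"]))


def write_summary_table(summary: "TrendSummary", path: str | os.PathLike) -> None:
    """Write the per-country trend decomposition table.

    Columns: ``country_id,s_i_median,b1i_median,b0_plus_b1i_median,
    trend_class``.  Values round-trip to 12 significant digits.
    """
    n = len(summary.countries)
    if n == 0:
        raise ValueError("cannot write an empty trend summary")
    lines = ["country_id,s_i_median,b1i_median,b0_plus_b1i_median,trend_class"]
    for i, c in enumerate(summary.countries):
        lines.append(
            f"{c},{summary.s_i_median[i]:.12g},{summary.b1i_median[i]:.12g},"
            f"{summary.b0_plus_b1i_median[i]:.12g},{summary.trend_class[i]}"
        )
    _atomic_write_text(path, "\n".join(lines) + "\n")


def read_summary_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a summary table written by :func:`write_summary_table`."""
    df = pd.read_csv(path)
    expected = ["country_id", "s_i_median", "b1i_median", "b0_plus_b1i_median", "trend_class"]
    if list(df.columns) != expected:
        raise ValueError(f"summary table must have columns {expected}")
    return df
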