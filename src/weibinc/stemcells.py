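"""Stem-cell divisions and their correlation with cancer incidence.

A tissue with ``S`` stem cells each dividing ``d`` times per year
accumulates ``LSCD(a) = S * d * a`` divisions by age ``a`` (lifetime stem
cell divisions).  The package ships a per-tissue table of literature
estimates of ``S`` and ``d`` and provides the log-log correlation and
regression machinery used to relate cumulative incidence at a given age to
LSCD across tissues.

By default the ``log2(S)`` developmental divisions that build the tissue
are excluded, so LSCD is proportional to age and vanishes at birth; the
``include_development`` flag adds the ``S - 1`` divisions of the
developmental binary expansion instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .data import AgeIncidenceSeries
from .fitting import DegenerateInputError

__all__ = [
    "StemCellRecord",
    "load_stem_cell_table",
    "lscd",
    "LogLogFit",
    "loglog_correlation",
    "age_stratified_correlation",
]


@dataclass(frozen=True)
class StemCellRecord:
    """Stem-cell parameters of one tissue/cancer type."""

    cancer: str
    stem_cells: float
    division_rate: float

    def __post_init__(self):
        if not self.stem_cells >= 1:
            raise ValueError(f"stem_cells must be >= 1, got {self.stem_cells}")
        if not self.division_rate >= 0:
            raise ValueError(f"division_rate must be >= 0, got {self.division_rate}")


def load_stem_cell_table(path=None) -> pd.DataFrame:
    """Load the per-tissue stem-cell table (packaged copy by default).

    Columns: cancer, stem_cells, division_rate.
    """
    if path is None:
        ref = resources.files("weibinc.datasets") / "stem_cells.csv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p, comment="#")
    return pd.read_csv(path, comment="#")


def records_from_table(df: pd.DataFrame) -> dict:
    """Turn the stem-cell table into a mapping label -> StemCellRecord."""
    return {
        row.cancer: StemCellRecord(cancer=row.cancer, stem_cells=float(row.stem_cells),
                                   division_rate=float(row.division_rate))
        for row in df.itertuples()
    }


def lscd(record: StemCellRecord, a, include_development: bool = False):
    """Cumulative stem-cell divisions of a tissue up to age ``a``.

    ``S * d * a`` by default; with ``include_development`` the ``S - 1``
    divisions of the developmental expansion are added (the two variants
    differ by exactly ``S - 1``).
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be >= 0")
    out = record.stem_cells * record.division_rate * a
    if include_development:
        out = out + (record.stem_cells - 1.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class LogLogFit:
    """Pearson correlation and least-squares line on log10-log10 axes."""

    rho: float
    slope: float
    intercept: float
    n: int


def loglog_correlation(x, y, labels=None) -> LogLogFit:
    """Correlation and regression of ``log10(y)`` on ``log10(x)``.

    Both inputs must be strictly positive; offending entries are reported
    by label (or index) in the error message.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    bad = np.nonzero((x <= 0) | (y <= 0))[0]
    if bad.size:
        names = [str(labels[i]) if labels is not None else str(i) for i in bad]
        raise ValueError(f"non-positive values at: {', '.join(names)}")
    lx, ly = np.log10(x), np.log10(y)
    if np.ptp(lx) == 0 or np.ptp(ly) == 0:
        raise DegenerateInputError("zero variance on a log axis")
    fit = stats.linregress(lx, ly)
    return LogLogFit(rho=float(fit.rvalue), slope=float(fit.slope),
                     intercept=float(fit.intercept), n=int(x.size))


def _cuminc_at(series: AgeIncidenceSeries, age: float) -> float:
    """Cumulative incidence up to (calendar) age ``age``.

    With 1-year bins at midpoints, incidence up to age ``a`` is the value of
    the last bin whose midpoint lies below ``a``.
    """
    idx = np.searchsorted(series.ages, age) - 1
    if idx < 0 or age > series.ages[-1] + 0.5:
        raise ValueError(
            f"{series.label}: requested age {age} outside the series range "
            f"[{series.ages[0]}, {series.ages[-1]}]"
        )
    return float(series.cuminc[idx])


def age_stratified_correlation(series_map, records, ages=(40, 50, 60, 70, 80),
                               include_development: bool = False) -> pd.DataFrame:
    """Correlate cumulative incidence with LSCD across tissues, per age.

    Parameters
    ----------
    series_map : dict
        Mapping label -> AgeIncidenceSeries (one per tissue).
    records : dict
        Mapping label -> StemCellRecord; every series label must match.
    ages : sequence
        Ages at which incidence and divisions are compared across tissues.

    Returns
    -------
    DataFrame with one row per age: (age, rho, slope, intercept, n).
    """
    unmatched = sorted(set(series_map) - set(records))
    if unmatched:
        raise ValueError(f"no stem-cell record for: {', '.join(unmatched)}")
    labels = sorted(series_map)
    rows = []
    for age in ages:
        inc = np.array([_cuminc_at(series_map[l], age) for l in labels])
        div = np.array([lscd(records[l], age, include_development=include_development)
                        for l in labels])
        fit = loglog_correlation(div, inc, labels=labels)
        rows.append({"age": age, "rho": fit.rho, "slope": fit.slope,
                     "intercept": fit.intercept, "n": fit.n})
    return pd.DataFrame(rows)
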