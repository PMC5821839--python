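"""Parameter sensitivity profiling and constrained tLIR grid search.

Two identifiability questions are addressed here.  First, how far can the
scaled-Weibull multiplier P and scale lambda move from their point estimates
before the fit degrades — profiled on a (P, lambda) grid with the shape k
re-estimated at every grid point.  Because the goodness metric is the
squared Pearson correlation, it is exactly invariant under rescaling of the
model curve, so the P axis of the good-fit region is unbounded in principle
and the reported span reflects the declared grid extent.  Second, whether
the four-parameter multistage tissue-risk model (tLIR) can reach a given
goodness of fit at all when the mutation rate is constrained to a plausible
range — answered by exhaustive grid search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .data import AgeIncidenceSeries, DEFAULT_MAX_AGE
from .fitting import (
    DegenerateInputError,
    IncidenceFitResults,
    ScaledWeibullModel,
    r_squared,
)
from .models import TlirParams, WeibullParams, weibull_cdf

__all__ = [
    "SensitivityGrid",
    "TlirSearchResult",
    "weibull_sensitivity",
    "k_robustness",
    "TlirModel",
    "tlir_grid_search",
    "good_fit_attainable",
    "DEFAULT_R_RANGE",
]

DEFAULT_R_RANGE = (1e-10, 1e-6)


# ---------------------------------------------------------------------------
# Weibull sensitivity
# ---------------------------------------------------------------------------

@dataclass
class SensitivityGrid:
    """R² surface over a (P, lambda) grid with a good-fit mask.

    ``surface[i, j]`` is the R² at ``P_grid[i], lambda_grid[j]`` (with the
    shape refit there when ``refit_k`` was set); ``k_surface`` holds the
    shape used at each point.  ``span`` maps each axis name to the ratio
    max/min of grid values participating in the good-fit mask.
    """

    P_grid: np.ndarray
    lambda_grid: np.ndarray
    surface: np.ndarray
    k_surface: np.ndarray
    threshold: float
    refit_k: bool
    base_params: WeibullParams
    mask: np.ndarray = field(init=False)
    span: dict = field(init=False)

    def __post_init__(self):
        self.mask = self.surface >= self.threshold
        self.span = {}
        if self.mask.any():
            p_in = self.P_grid[self.mask.any(axis=1)]
            l_in = self.lambda_grid[self.mask.any(axis=0)]
            self.span = {"P": float(p_in.max() / p_in.min()),
                         "lambda": float(l_in.max() / l_in.min())}

    def span_orders(self, axis: str) -> float:
        """Good-fit span of an axis in orders of magnitude (log10 of the ratio)."""
        if axis not in self.span:
            raise ValueError(f"no good-fit span for axis {axis!r} (empty mask?)")
        return float(np.log10(self.span[axis]))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns (P, lambda, k_refit, r_squared)."""
        P, L = np.meshgrid(self.P_grid, self.lambda_grid, indexing="ij")
        return pd.DataFrame({
            "P": P.ravel(),
            "lambda": L.ravel(),
            "k_refit": self.k_surface.ravel(),
            "r_squared": self.surface.ravel(),
        })


def weibull_sensitivity(series: AgeIncidenceSeries, base_fit: IncidenceFitResults,
                        P_grid, lambda_grid, threshold: float = 0.99,
                        refit_k: bool = True, k_bounds=(0.2, 20.0),
                        max_age: float = DEFAULT_MAX_AGE) -> SensitivityGrid:
    """Profile the R² surface over a (P, lambda) grid.

    At every grid point the shape k is re-estimated (by maximizing R², which
    is what the correlation metric rewards — refitting by SSE at a displaced
    P would drag k into compensating for the wrong scale) unless ``refit_k``
    is false, in which case the base fit's k is held.
    """
    P_grid = np.asarray(P_grid, dtype=float)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if P_grid.size == 0 or lambda_grid.size == 0:
        raise ValueError("sensitivity grids must be non-empty")
    if np.any(P_grid <= 0) or np.any(lambda_grid <= 0):
        raise ValueError("grid values must be strictly positive")
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in the open interval (0, 1), got {threshold}")

    trunc = series.truncate(max_age)
    ages, emp = trunc.ages, trunc.cuminc
    base_k = base_fit.params.k

    surface = np.empty((P_grid.size, lambda_grid.size))
    k_surface = np.empty_like(surface)
    for j, lam in enumerate(lambda_grid):
        if refit_k:
            def neg_r2(k, lam=lam):
                try:
                    return -r_squared(emp, weibull_cdf(ages, lam, k))
                except DegenerateInputError:
                    return 0.0
            sol = optimize.minimize_scalar(neg_r2, bounds=k_bounds, method="bounded",
                                           options={"xatol": 1e-6})
            k_use, r2 = float(sol.x), float(-sol.fun)
        else:
            k_use = base_k
            try:
                r2 = r_squared(emp, weibull_cdf(ages, lam, base_k))
            except DegenerateInputError:
                r2 = 0.0
        # R² is invariant under the positive scaling by P: one column per lambda
        surface[:, j] = r2
        k_surface[:, j] = k_use
    return SensitivityGrid(P_grid=P_grid, lambda_grid=lambda_grid, surface=surface,
                           k_surface=k_surface, threshold=threshold, refit_k=refit_k,
                           base_params=base_fit.params)


def k_robustness(subgroup_series, n_starts: int = 20, seed: int = 0,
                 spread_flag: float = 2.0, max_age: float = DEFAULT_MAX_AGE):
    """Fit the scaled Weibull per subgroup and summarize the shape estimates.

    Returns
    -------
    (DataFrame, dict)
        Per-subgroup table (label, P, lambda, k, r_squared, error) and a
        summary with median/min/max/spread of fitted k plus a
        ``non_uniform`` flag raised when the spread exceeds ``spread_flag``.
    """
    subgroup_series = list(subgroup_series)
    if len(subgroup_series) < 2:
        raise ValueError("need at least 2 subgroup series")
    rows = []
    for s in subgroup_series:
        try:
            res = ScaledWeibullModel(s, max_age=max_age).fit(n_starts=n_starts, seed=seed)
            rows.append({"label": s.label, "P": res.params.P, "lambda": res.params.lambda_,
                         "k": res.params.k, "r_squared": res.r_squared, "error": ""})
        except Exception as exc:
            rows.append({"label": s.label, "P": np.nan, "lambda": np.nan,
                         "k": np.nan, "r_squared": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows)
    ks = table["k"].dropna()
    if ks.empty:
        raise ValueError("no subgroup could be fitted: "
                         + "; ".join(f"{r['label']}: {r['error']}" for r in rows))
    spread = float(ks.max() - ks.min())
    summary = {
        "n_subgroups": len(subgroup_series),
        "n_fitted": int(ks.size),
        "k_median": float(ks.median()),
        "k_min": float(ks.min()),
        "k_max": float(ks.max()),
        "k_spread": spread,
        "non_uniform": spread > spread_flag,
        "failed_labels": table.loc[table["error"] != "", "label"].tolist(),
    }
    return table, summary


# ---------------------------------------------------------------------------
# tLIR grid search
# ---------------------------------------------------------------------------

@dataclass
class TlirSearchResult:
    """Outcome of an exhaustive tLIR grid search.

    ``table`` holds one row per evaluated (S, r, d, k) combination with its
    R² against the empirical curve; ``params`` is the best combination.
    """

    params: TlirParams
    r_squared: float
    table: pd.DataFrame
    r_range: tuple

    def summary(self) -> str:
        p = self.params
        return (f"tLIR grid search over {len(self.table)} combinations "
                f"(r restricted to [{self.r_range[0]:g}, {self.r_range[1]:g}])\n"
                f"best: S={p.S:g}, r={p.r:g}, d={p.d:g}, k={p.k:g}  "
                f"R2={self.r_squared:.6f}")


def _default_grids():
    return {
        "S": np.logspace(4, 11, 8),
        "r": np.logspace(-10, -6, 13),
        "d": np.logspace(-2, 2, 9),
        "k": np.arange(1.0, 10.0 + 1e-9, 0.1),
    }


class TlirModel:
    """Four-parameter multistage tissue-risk model fitted by grid search.

    The closed-form risk curve ``1 - (1 - (1 - (1-r)^(log2 S + d a))^k)^S``
    is evaluated for every combination of the S/r/d/k grids and scored by
    squared Pearson correlation with the empirical cumulative incidence; the
    search is exhaustive and therefore deterministic for a fixed grid.
    """

    def __init__(self, series: AgeIncidenceSeries, max_age: float = DEFAULT_MAX_AGE):
        self.series = series.truncate(max_age)
        self.ages = self.series.ages
        self.endog = self.series.cuminc
        if self.endog.size < 3 or np.ptp(self.endog) == 0:
            raise DegenerateInputError(
                f"{series.label}: empirical curve has no variance; tLIR search undefined"
            )

    def fit(self, S_grid=None, r_grid=None, d_grid=None, k_grid=None,
            r_range=DEFAULT_R_RANGE, chunk: int = 4096) -> TlirSearchResult:
        """Exhaustive search over the Cartesian product of the grids.

        The r grid is clipped to ``r_range`` (a warning is issued when
        values fall outside); division rate 0 is rejected as unsearchable
        because the risk curve is then constant in age.
        """
        defaults = _default_grids()
        S_grid = np.asarray(defaults["S"] if S_grid is None else S_grid, float)
        r_grid = np.asarray(defaults["r"] if r_grid is None else r_grid, float)
        d_grid = np.asarray(defaults["d"] if d_grid is None else d_grid, float)
        k_grid = np.asarray(defaults["k"] if k_grid is None else k_grid, float)
        for name, g in (("S", S_grid), ("r", r_grid), ("d", d_grid), ("k", k_grid)):
            if g.size == 0:
                raise ValueError(f"empty grid for {name}")
        if np.any(d_grid <= 0):
            raise ValueError("division rate 0 is unsearchable: the risk curve is flat in age")
        lo, hi = r_range
        outside = (r_grid < lo) | (r_grid > hi)
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} r grid values outside [{lo:g}, {hi:g}] were clipped",
                UserWarning, stacklevel=2)
            r_grid = np.clip(r_grid, lo, hi)
            r_grid = np.unique(r_grid)

        S, r, d, k = (g.ravel() for g in np.meshgrid(S_grid, r_grid, d_grid, k_grid,
                                                     indexing="ij"))
        ages = self.ages
        emp = self.endog
        emp_c = emp - emp.mean()
        emp_norm = np.sqrt(emp_c @ emp_c)

        r2_all = np.empty(S.size)
        for start in range(0, S.size, chunk):
            sl = slice(start, min(start + chunk, S.size))
            n = np.log2(S[sl])[:, None] + d[sl][:, None] * ages[None, :]
            with np.errstate(divide="ignore"):
                q = -np.expm1(n * np.log1p(-r[sl])[:, None])
                inner = q ** k[sl][:, None]
                curves = -np.expm1(S[sl][:, None] * np.log1p(-inner))
            c = curves - curves.mean(axis=1, keepdims=True)
            norm = np.sqrt(np.einsum("ij,ij->i", c, c))
            with np.errstate(invalid="ignore", divide="ignore"):
                rho = (c @ emp_c) / (norm * emp_norm)
            r2 = rho ** 2
            r2[~np.isfinite(r2)] = np.nan  # zero-variance model curves
            r2_all[sl] = np.minimum(r2, 1.0)

        table = pd.DataFrame({"S": S, "r": r, "d": d, "k": k, "r_squared": r2_all})
        if np.all(np.isnan(r2_all)):
            raise DegenerateInputError("every model curve on the grid is constant in age")
        best_idx = int(np.nanargmax(r2_all))
        best = TlirParams(S=float(S[best_idx]), r=float(r[best_idx]),
                          d=float(d[best_idx]), k=float(k[best_idx]))
        return TlirSearchResult(params=best, r_squared=float(r2_all[best_idx]),
                                table=table, r_range=tuple(r_range))


def tlir_grid_search(series, S_grid=None, r_grid=None, d_grid=None, k_grid=None,
                     r_range=DEFAULT_R_RANGE, max_age=DEFAULT_MAX_AGE) -> TlirSearchResult:
    """Constrained exhaustive tLIR parameter search (convenience wrapper)."""
    return TlirModel(series, max_age=max_age).fit(
        S_grid=S_grid, r_grid=r_grid, d_grid=d_grid, k_grid=k_grid, r_range=r_range)


def good_fit_attainable(series, threshold: float = 0.85, S_grid=None, r_grid=None,
                        d_grid=None, k_grid=None, r_range=DEFAULT_R_RANGE,
                        max_age=DEFAULT_MAX_AGE):
    """Can the constrained tLIR model reach R² >= ``threshold`` on this curve?

    Returns
    -------
    (bool, TlirSearchResult)
        True with the best grid point as witness when any combination
        reaches the threshold; False with the best-found result otherwise.
    """
    result = tlir_grid_search(series, S_grid=S_grid, r_grid=r_grid, d_grid=d_grid,
                              k_grid=k_grid, r_range=r_range, max_age=max_age)
    return bool(result.r_squared >= threshold), result
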