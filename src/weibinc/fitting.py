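"""Fit incidence models to cumulative curves and compare them.

The estimation objective is least squares on the cumulative incidence
curve; the goodness-of-fit metric reported alongside is the squared Pearson
correlation between the empirical and fitted curves (scale-free, so it
cannot identify the multiplier P by itself — least squares pins the scale).
When diagnosis counts are available, a per-age-bin binomial likelihood of
the fitted curve yields a log-likelihood and AIC for model comparison.

The module is organised statsmodels-style: a model class is constructed
from an :class:`~weibinc.data.AgeIncidenceSeries` and its ``fit`` method
returns an :class:`IncidenceFitResults` carrying the parameter bundle,
diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import AgeIncidenceSeries, DEFAULT_MAX_AGE
from .models import (
    GammaParams,
    PowerLawParams,
    WeibullParams,
    power_law_incidence,
    scaled_gamma_incidence,
    scaled_weibull_incidence,
)

__all__ = [
    "DegenerateInputError",
    "UnfittableSeriesError",
    "r_squared",
    "binomial_loglik",
    "aic",
    "IncidenceFitResults",
    "ScaledWeibullModel",
    "ScaledGammaModel",
    "PowerLawModel",
    "fit_scaled_weibull",
    "fit_scaled_gamma",
    "fit_power_law",
    "compare_models",
    "MODEL_FAMILIES",
]


class DegenerateInputError(ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class UnfittableSeriesError(ValueError):
    """The series cannot support a fit (too short, all-zero, ...)."""


def r_squared(x, y) -> float:
    """Squared Pearson correlation between two curves.

    ``R^2 = (sum((x-xbar)(y-ybar)) / sqrt(sum((x-xbar)^2) sum((y-ybar)^2)))^2``

    Invariant under positive affine transforms of either argument.  Zero
    variance in either vector raises :class:`DegenerateInputError` rather
    than silently returning 0 or 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    dx = x - x.mean()
    dy = y - y.mean()
    vx = dx @ dx
    vy = dy @ dy
    if vx == 0 or vy == 0:
        raise DegenerateInputError("zero variance input to r_squared")
    r = (dx @ dy) / np.sqrt(vx * vy)
    return float(min(r * r, 1.0))


def binomial_loglik(series: AgeIncidenceSeries, model_curve) -> float:
    """Binomial log-likelihood of a model cumulative curve given counts.

    The model's per-bin conditional diagnosis probability is the discrete
    hazard ``q_a = (F(a) - F(a-)) / (1 - F(a-))`` with ``F(-) = 0`` at the
    first bin; each bin contributes ``log Binom(x_a; n_a, q_a)``.  A bin
    with model probability 0 but a nonzero count makes the likelihood
    -inf; this is returned with an explicit warning rather than silently.
    """
    if not series.has_counts:
        raise ValueError("series has no counts; binomial likelihood undefined")
    F = np.asarray(model_curve, dtype=float)
    if F.shape != series.ages.shape:
        raise ValueError("model curve must match the series age grid")
    if np.any(F < 0) or np.any(F >= 1) or np.any(np.diff(F) < 0):
        raise ValueError("model curve must be non-decreasing and in [0, 1)")
    F_prev = np.concatenate([[0.0], F[:-1]])
    q = (F - F_prev) / (1.0 - F_prev)
    q = np.clip(q, 0.0, 1.0)
    ll = float(np.sum(stats.binom.logpmf(series.diagnosed, series.at_risk, q)))
    if not np.isfinite(ll):
        warnings.warn(
            "model assigns probability 0 to a bin with a nonzero count; "
            "log-likelihood is -inf",
            RuntimeWarning,
            stacklevel=2,
        )
    return ll


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion ``2 * n_params - 2 * loglik`` (lower is better)."""
    if not np.isfinite(loglik):
        raise ValueError("AIC requires a finite log-likelihood")
    return 2.0 * n_params - 2.0 * loglik


# ---------------------------------------------------------------------------
# Results object
# ---------------------------------------------------------------------------

@dataclass
class IncidenceFitResults:
    """Fitted parameters and diagnostics for one model family.

    Attributes
    ----------
    family : str
        ``"weibull"``, ``"gamma"`` or ``"powerlaw"``.
    params : parameter bundle
        WeibullParams / GammaParams / PowerLawParams.
    r_squared : float
        Squared Pearson correlation of fitted vs empirical curve.
    sse : float
        Sum of squared residuals of the least-squares objective.
    loglik, aic : float or None
        Binomial log-likelihood and AIC; present when counts exist.
    """

    family: str
    params: object
    r_squared: float
    sse: float
    n_points: int
    loglik: float = None
    aic: float = None
    fittedvalues: np.ndarray = None
    model: object = None
    converged: bool = True

    @property
    def n_free_params(self) -> int:
        return len(self.params.to_dict())

    def summary(self) -> str:
        lines = [
            f"{self.family} incidence fit ({self.n_points} age bins)",
            "-" * 46,
        ]
        for name, value in self.params.to_dict().items():
            lines.append(f"{name:>10s}  {value:.6g}")
        lines.append(f"{'R2':>10s}  {self.r_squared:.6f}")
        lines.append(f"{'SSE':>10s}  {self.sse:.6g}")
        if self.loglik is not None:
            lines.append(f"{'loglik':>10s}  {self.loglik:.4f}")
            lines.append(f"{'AIC':>10s}  {self.aic:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": self.params.to_dict(),
            "r_squared": self.r_squared,
            "sse": self.sse,
            "n_points": self.n_points,
            "loglik": self.loglik,
            "aic": self.aic,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# Model classes
# ---------------------------------------------------------------------------

class _IncidenceModel:
    """Shared machinery: multi-start bounded least squares on the cumulative curve."""

    family: str = None
    n_free = None

    def __init__(self, series: AgeIncidenceSeries, max_age: float = DEFAULT_MAX_AGE):
        if not isinstance(series, AgeIncidenceSeries):
            raise TypeError("series must be an AgeIncidenceSeries")
        self.series = series.truncate(max_age)
        self.ages = self.series.ages
        self.endog = self.series.cuminc
        if len(self.series) < 4:
            raise UnfittableSeriesError(
                f"{series.label}: need at least 4 age bins, got {len(self.series)}"
            )
        if not np.any(self.endog > 0):
            raise UnfittableSeriesError(f"{series.label}: all-zero cumulative incidence")

    # subclass hooks -------------------------------------------------------
    def curve(self, theta, ages):
        raise NotImplementedError

    def make_params(self, theta):
        raise NotImplementedError

    def starts(self, rng, n_starts):
        raise NotImplementedError

    def bounds(self):
        raise NotImplementedError

    # ----------------------------------------------------------------------
    def fit(self, n_starts: int = 20, seed: int = 0) -> IncidenceFitResults:
        """Estimate parameters by multi-start bounded least squares.

        Optimization runs in log-parameter space (all parameters are
        positive); ``n_starts`` seeded starting points are tried and the
        lowest-SSE solution is kept.
        """
        rng = np.random.default_rng(seed)
        lo, hi = (np.log(b) for b in self.bounds())

        def resid(log_theta):
            return self.curve(np.exp(log_theta), self.ages) - self.endog

        best = None
        for theta0 in self.starts(rng, n_starts):
            x0 = np.clip(np.log(theta0), lo, hi)
            try:
                sol = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf")
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise UnfittableSeriesError(
                f"{self.series.label}: no optimizer start converged for {self.family}"
            )
        theta = np.exp(best.x)
        params = self.make_params(theta)
        fitted = self.curve(theta, self.ages)
        sse = float(np.sum((fitted - self.endog) ** 2))
        r2 = r_squared(self.endog, fitted)
        ll = a = None
        if self.series.has_counts:
            Fc = np.clip(fitted, 0.0, 1.0 - 1e-15)
            Fc = np.maximum.accumulate(Fc)
            ll = binomial_loglik(self.series, Fc)
            a = aic(ll, self.n_free) if np.isfinite(ll) else np.inf
        return IncidenceFitResults(
            family=self.family,
            params=params,
            r_squared=r2,
            sse=sse,
            n_points=len(self.series),
            loglik=ll,
            aic=a,
            fittedvalues=fitted,
            model=self,
            converged=bool(best.success),
        )


class ScaledWeibullModel(_IncidenceModel):
    """``cuminc(a) = P * (1 - exp(-(a/lambda)**k))`` fitted to a series."""

    family = "weibull"
    n_free = 3

    def curve(self, theta, ages):
        P, lam, k = theta
        return P * -np.expm1(-((ages / lam) ** k))

    def make_params(self, theta):
        return WeibullParams(P=float(theta[0]), lambda_=float(theta[1]), k=float(theta[2]))

    def bounds(self):
        top = self.endog.max()
        return (np.array([top * 1e-6, 1.0, 0.05]),
                np.array([max(top * 1e6, 1e6), 1e7, 50.0]))

    def starts(self, rng, n_starts):
        top = self.endog.max()
        yield np.array([top, 100.0, 4.0])  # deterministic heuristic start
        for _ in range(max(n_starts - 1, 0)):
            yield np.array([
                top * 10 ** rng.uniform(-4, 2),
                10 ** rng.uniform(np.log10(20), np.log10(500)),
                rng.uniform(1.0, 10.0),
            ])


class ScaledGammaModel(_IncidenceModel):
    """``cuminc(a) = P * GammaCDF(a; shape, scale)`` fitted to a series."""

    family = "gamma"
    n_free = 3

    def curve(self, theta, ages):
        from scipy import special
        P, shape, scale = theta
        return P * special.gammainc(shape, ages / scale)

    def make_params(self, theta):
        return GammaParams(P=float(theta[0]), shape=float(theta[1]), scale=float(theta[2]))

    def bounds(self):
        top = self.endog.max()
        return (np.array([top * 1e-6, 0.05, 0.1]),
                np.array([max(top * 1e6, 1e6), 100.0, 1e5]))

    def starts(self, rng, n_starts):
        top = self.endog.max()
        yield np.array([top, 4.0, 20.0])
        for _ in range(max(n_starts - 1, 0)):
            yield np.array([
                top * 10 ** rng.uniform(-4, 2),
                rng.uniform(0.5, 15.0),
                10 ** rng.uniform(np.log10(2), np.log10(200)),
            ])


class PowerLawModel(_IncidenceModel):
    """``cuminc(a) = c * a**m`` fitted in the original (not log) space.

    A log-log regression on the positive part of the curve provides the
    main starting point; set ``log_space=True`` on ``fit`` for the
    alternative log-space objective.
    """

    family = "powerlaw"
    n_free = 2

    def __init__(self, series, max_age: float = DEFAULT_MAX_AGE):
        super().__init__(series, max_age)
        if np.any(self.ages <= 0):
            raise UnfittableSeriesError("power law requires strictly positive ages")

    def curve(self, theta, ages):
        c, m = theta
        return c * ages ** m

    def make_params(self, theta):
        return PowerLawParams(c=float(theta[0]), m=float(theta[1]))

    def bounds(self):
        return (np.array([1e-30, 1e-3]), np.array([1e3, 30.0]))

    def _loglog_start(self):
        pos = self.endog > 0
        if pos.sum() >= 2:
            slope, intercept = np.polyfit(np.log(self.ages[pos]), np.log(self.endog[pos]), 1)
            return np.array([np.exp(intercept), max(slope, 1e-3)])
        return np.array([self.endog.max() / self.ages.max() ** 4, 4.0])

    def starts(self, rng, n_starts):
        yield self._loglog_start()
        for _ in range(max(n_starts - 1, 0)):
            m = rng.uniform(0.5, 10.0)
            c = self.endog.max() / self.ages.max() ** m * 10 ** rng.uniform(-1, 1)
            yield np.array([c, m])

    def fit(self, n_starts: int = 20, seed: int = 0, log_space: bool = False):
        if not log_space:
            return super().fit(n_starts=n_starts, seed=seed)
        pos = self.endog > 0
        if pos.sum() < 3:
            raise UnfittableSeriesError("too few positive bins for a log-space power-law fit")
        slope, intercept = np.polyfit(np.log(self.ages[pos]), np.log(self.endog[pos]), 1)
        theta = np.array([np.exp(intercept), slope])
        if theta[1] <= 0:
            raise UnfittableSeriesError("log-space power-law slope is non-positive")
        fitted = self.curve(theta, self.ages)
        sse = float(np.sum((fitted - self.endog) ** 2))
        res = IncidenceFitResults(
            family=self.family, params=self.make_params(theta),
            r_squared=r_squared(self.endog, fitted), sse=sse,
            n_points=len(self.series), fittedvalues=fitted, model=self,
        )
        if self.series.has_counts:
            Fc = np.maximum.accumulate(np.clip(fitted, 0.0, 1.0 - 1e-15))
            res.loglik = binomial_loglik(self.series, Fc)
            res.aic = aic(res.loglik, self.n_free) if np.isfinite(res.loglik) else np.inf
        return res


MODEL_FAMILIES = {
    "weibull": ScaledWeibullModel,
    "gamma": ScaledGammaModel,
    "powerlaw": PowerLawModel,
}


def fit_scaled_weibull(series, n_starts=20, seed=0, max_age=DEFAULT_MAX_AGE):
    """Fit the scaled Weibull family to a series (convenience wrapper)."""
    return ScaledWeibullModel(series, max_age=max_age).fit(n_starts=n_starts, seed=seed)


def fit_scaled_gamma(series, n_starts=20, seed=0, max_age=DEFAULT_MAX_AGE):
    """Fit the scaled Gamma family to a series (convenience wrapper)."""
    return ScaledGammaModel(series, max_age=max_age).fit(n_starts=n_starts, seed=seed)


def fit_power_law(series, n_starts=20, seed=0, max_age=DEFAULT_MAX_AGE, log_space=False):
    """Fit the power-law family to a series (convenience wrapper)."""
    return PowerLawModel(series, max_age=max_age).fit(
        n_starts=n_starts, seed=seed, log_space=log_space
    )


def compare_models(series, families=("weibull", "gamma", "powerlaw"),
                   n_starts=20, seed=0, max_age=DEFAULT_MAX_AGE):
    """Fit several families to one series and rank them.

    Ranking uses AIC when counts are available, otherwise R² (higher is
    better); exact ties go to the family with fewer free parameters.
    Families that fail to fit are kept in the table with their error
    message rather than dropped.

    Returns
    -------
    (DataFrame, dict)
        The ranked comparison table and a mapping family -> results object
        (or the raised exception for failed families).
    """
    families = list(families)
    if len(families) < 2:
        raise ValueError("need at least 2 model families to compare")
    unknown = [f for f in families if f not in MODEL_FAMILIES]
    if unknown:
        raise ValueError(f"unknown model families: {unknown}")

    results = {}
    rows = []
    for fam in families:
        try:
            res = MODEL_FAMILIES[fam](series, max_age=max_age).fit(n_starts=n_starts, seed=seed)
            results[fam] = res
            row = {"label": series.label, "family": fam, "r_squared": res.r_squared,
                   "sse": res.sse, "loglik": res.loglik, "aic": res.aic,
                   "n_params": res.n_free_params, "error": ""}
            row.update({f"param_{k}": v for k, v in res.params.to_dict().items()})
            rows.append(row)
        except Exception as exc:  # report, never drop silently
            results[fam] = exc
            rows.append({"label": series.label, "family": fam, "r_squared": np.nan,
                         "sse": np.nan, "loglik": None, "aic": None,
                         "n_params": MODEL_FAMILIES[fam].n_free, "error": str(exc)})
    table = pd.DataFrame(rows)
    ok = table["error"] == ""
    use_aic = series.has_counts and table.loc[ok, "aic"].notna().all()
    if use_aic:
        key = table["aic"].astype(float)
        order = np.lexsort((table["n_params"], key.round(12)))
    else:
        key = -table["r_squared"].astype(float)
        order = np.lexsort((table["n_params"], key.round(12)))
    # failed fits always rank last
    order = np.concatenate([
        [i for i in order if ok.iloc[i]],
        [i for i in order if not ok.iloc[i]],
    ]).astype(int)
    table = table.iloc[order].reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table, results
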