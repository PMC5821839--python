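"""Model families for age-dependent cancer incidence.

This module collects the closed-form curves used throughout the package:

* the multistage driver-mutation recursion for a single stem-cell lineage
  and its closed-form solution,
* the theoretical lifetime intrinsic risk (tLIR) of a tissue of ``S`` stem
  cells, each of which must accumulate ``k`` driver events over
  ``log2(S) + d*a`` divisions at per-division mutation probability ``r``,
* the scaled Weibull approximation ``P * (1 - exp(-(a/lambda)**k))`` and its
  saturating variant ``1 - (1 - Weibull)**P``,
* a scaled Gamma alternative and the classical multistage power law.

All curve functions accept scalar or array ages and are carefully formulated
with ``log1p``/``expm1`` so that probabilities far below ``1/S`` (down to
~1e-300) survive the tissue-level compounding without underflowing to zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import special, stats

__all__ = [
    "TlirParams",
    "WeibullParams",
    "GammaParams",
    "PowerLawParams",
    "MutationPmf",
    "weibull_cdf",
    "scaled_weibull_incidence",
    "scaled_weibull_saturating",
    "mutation_pmf_recursion",
    "mutation_hit_prob_closed_form",
    "tissue_risk",
    "tlir",
    "generations",
    "lambda_from_tlir",
    "scaled_gamma_incidence",
    "power_law_incidence",
]


# ---------------------------------------------------------------------------
# Parameter bundles
# ---------------------------------------------------------------------------

class _JsonParamsMixin:
    """Serialize parameter bundles to/from JSON with their field names."""

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict):
        return cls(**d)

    @classmethod
    def from_json(cls, s: str):
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class TlirParams(_JsonParamsMixin):
    """Parameters of the multistage tissue-risk model.

    S : stem cell count of the tissue (>= 1, real-valued)
    r : mutation probability per driver target per division, in [0, 1)
    d : stem cell division rate (divisions per stem cell per year, >= 0)
    k : number of driver events required for onset (> 0; real values are
        admissible because the closed form extends the integer recursion)
    """

    S: float
    r: float
    d: float
    k: float

    def __post_init__(self):
        if not self.S >= 1:
            raise ValueError(f"S must be >= 1, got {self.S}")
        if not (0 <= self.r < 1):
            raise ValueError(f"r must be in [0, 1), got {self.r}")
        if not self.d >= 0:
            raise ValueError(f"d must be >= 0, got {self.d}")
        if not self.k > 0:
            raise ValueError(f"k must be > 0, got {self.k}")


@dataclass(frozen=True)
class WeibullParams(_JsonParamsMixin):
    """Scaled-Weibull incidence parameters.

    P      : scale multiplier, interpretable as the cell population at risk
             (number of independent parallel processes), > 0
    lambda_: Weibull scale in years, > 0 (serialized as ``lambda``)
    k      : Weibull shape, > 0; corresponds to the number of driver events
    """

    P: float
    lambda_: float
    k: float

    def __post_init__(self):
        for name in ("P", "lambda_", "k"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name.rstrip('_')} must be > 0, got {getattr(self, name)}")

    def to_dict(self) -> dict:
        return {"P": self.P, "lambda": self.lambda_, "k": self.k}

    @classmethod
    def from_dict(cls, d: dict):
        d = dict(d)
        if "lambda" in d:
            d["lambda_"] = d.pop("lambda")
        return cls(**d)


@dataclass(frozen=True)
class GammaParams(_JsonParamsMixin):
    """Scaled-Gamma incidence parameters: P * GammaCDF(a; shape, scale)."""

    P: float
    shape: float
    scale: float

    def __post_init__(self):
        for name in ("P", "shape", "scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class PowerLawParams(_JsonParamsMixin):
    """Power-law incidence parameters: c * a**m."""

    c: float
    m: float

    def __post_init__(self):
        if not self.c > 0:
            raise ValueError(f"c must be > 0, got {self.c}")
        if not self.m > 0:
            raise ValueError(f"m must be > 0, got {self.m}")


@dataclass(frozen=True)
class MutationPmf:
    """Distribution of accumulated driver hits in one lineage.

    ``probs[i]`` is the probability that a cell carries ``i`` of the ``k``
    driver targets after ``g`` divisions at per-division hit probability
    ``r``.  The vector always has length ``k + 1`` and sums to one.
    """

    k: int
    g: int
    r: float
    probs: np.ndarray = field(repr=False)

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (self.k + 1,):
            raise ValueError("probs must have length k + 1")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1 within 1e-12")
        object.__setattr__(self, "probs", p)


# ---------------------------------------------------------------------------
# Scaled Weibull
# ---------------------------------------------------------------------------

def weibull_cdf(a, lambda_: float, k: float):
    """Weibull cumulative distribution function ``1 - exp(-(a/lambda)**k)``.

    Parameters
    ----------
    a : array_like
        Age(s) in years, >= 0.
    lambda_ : float
        Scale parameter in years, > 0.
    k : float
        Shape parameter, > 0.
    """
    if not lambda_ > 0:
        raise ValueError(f"lambda must be > 0, got {lambda_}")
    if not k > 0:
        raise ValueError(f"k must be > 0, got {k}")
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be >= 0")
    out = -np.expm1(-((a / lambda_) ** k))
    return out if out.ndim else float(out)


def scaled_weibull_incidence(a, params: WeibullParams):
    """Cumulative incidence ``P * Weibull(lambda, k)(a)``.

    The linear scaling is the first-order (Poisson) approximation of the
    saturating form and is the model fitted to empirical curves.
    """
    return params.P * weibull_cdf(a, params.lambda_, params.k)


def scaled_weibull_saturating(a, params: WeibullParams):
    """Saturating form ``1 - (1 - Weibull(lambda, k)(a))**P``.

    Probability that at least one of ``P`` independent parallel processes
    has fired by age ``a``; always in [0, 1] and bounded above by the linear
    form ``P * Weibull``.
    """
    w = weibull_cdf(a, params.lambda_, params.k)
    out = -np.expm1(params.P * np.log1p(-np.asarray(w, dtype=float)))
    return out if np.ndim(a) else float(out)


# ---------------------------------------------------------------------------
# Driver-mutation recursion and closed form
# ---------------------------------------------------------------------------

def mutation_pmf_recursion(k: int, g: int, r: float) -> MutationPmf:
    """Exact hit distribution after ``g`` divisions of one lineage.

    Starting from the point mass at zero hits, each division mutates every
    one of the remaining ``k - j`` intact driver targets independently with
    probability ``r``, so the transition from ``j`` to ``i >= j`` hits has
    probability ``C(k-j, i-j) * r**(i-j) * (1-r)**(k-i)``.  The transition
    is applied ``g`` times.
    """
    if not (isinstance(k, (int, np.integer)) and k >= 0):
        raise ValueError(f"k must be a non-negative integer, got {k}")
    if not (isinstance(g, (int, np.integer)) and g >= 0):
        raise ValueError(f"g must be a non-negative integer, got {g}")
    if not (0 <= r < 1):
        raise ValueError(f"r must be in [0, 1), got {r}")

    # T[j, i] = P(i hits after division | j hits before) = Binom(k - j, r) at i - j
    idx = np.arange(k + 1)
    new_hits = idx[None, :] - idx[:, None]          # i - j
    remaining = k - idx[:, None]                    # k - j
    with np.errstate(invalid="ignore"):
        T = stats.binom.pmf(new_hits, remaining, r)
    T = np.where(new_hits < 0, 0.0, T)

    probs = np.zeros(k + 1)
    probs[0] = 1.0
    for _ in range(g):
        probs = probs @ T
    if g:  # each transition conserves mass exactly; remove accumulated rounding
        probs = probs / probs.sum()
    return MutationPmf(k=int(k), g=int(g), r=float(r), probs=probs)


def mutation_hit_prob_closed_form(k: float, g: float, r: float) -> float:
    """Closed form ``(1 - (1-r)**g)**k`` for the full-hit probability.

    Equals ``mutation_pmf_recursion(k, g, r).probs[k]`` for integer ``k``
    and ``g``; the closed form extends both to positive reals.
    """
    if not k > 0:
        raise ValueError(f"k must be > 0, got {k}")
    if not g >= 0:
        raise ValueError(f"g must be >= 0, got {g}")
    if not (0 <= r < 1):
        raise ValueError(f"r must be in [0, 1), got {r}")
    q = -math.expm1(g * math.log1p(-r))  # 1 - (1-r)^g, accurate for tiny r*g
    return q ** k


def tissue_risk(p_cell, S: float):
    """Tissue-level risk ``1 - (1 - p_cell)**S`` of at least one event.

    Formulated as ``-expm1(S * log1p(-p_cell))`` so that per-cell
    probabilities far below ``1/S`` do not underflow.
    """
    if not S >= 1:
        raise ValueError(f"S must be >= 1, got {S}")
    p = np.asarray(p_cell, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("per-cell probability must be in [0, 1]")
    with np.errstate(divide="ignore"):
        out = -np.expm1(S * np.log1p(-p))
    return out if out.ndim else float(out)


def generations(S: float, d: float, a: float) -> float:
    """Number of division rounds ``log2(S) + d * a`` a lineage has undergone.

    ``log2(S)`` rounds build the tissue of ``S`` stem cells; maintenance then
    adds ``d`` rounds per year.  Returned as a real number, not rounded.
    """
    if not S >= 1:
        raise ValueError(f"S must be >= 1, got {S}")
    if not d >= 0:
        raise ValueError(f"d must be >= 0, got {d}")
    if not a >= 0:
        raise ValueError(f"a must be >= 0, got {a}")
    return math.log2(S) + d * a


def tlir(a, params: TlirParams):
    """Theoretical lifetime intrinsic risk at age ``a``.

    ``tlir(a) = 1 - (1 - (1 - (1-r)**(log2 S + d a))**k)**S``: the chance
    that at least one of ``S`` stem cells has hit all ``k`` driver targets
    after its ``log2(S) + d*a`` divisions.  Generations are used real-valued.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be >= 0")
    n = math.log2(params.S) + params.d * a
    with np.errstate(divide="ignore"):
        q = -np.expm1(n * math.log1p(-params.r))   # 1 - (1-r)^n
        inner = q ** params.k                      # per-cell full-hit probability
        out = -np.expm1(params.S * np.log1p(-inner))
    return out if out.ndim else float(out)


def lambda_from_tlir(params: TlirParams, P: float) -> float:
    """Weibull scale implied by the parameter bridge ``S (r d)**k = P / lambda**k``.

    Solving for the scale gives ``lambda = (P / (S (r d)**k))**(1/k)``,
    computed in log space to avoid underflow of ``(r d)**k``.  With
    ``P = S`` this reduces to ``lambda = 1 / (r d)``.
    """
    if not (params.r > 0 and params.d > 0):
        raise ValueError("lambda is undefined for r = 0 or d = 0")
    if not P > 0:
        raise ValueError(f"P must be > 0, got {P}")
    log_lambda = (math.log(P) - math.log(params.S)) / params.k - math.log(params.r * params.d)
    return math.exp(log_lambda)


# ---------------------------------------------------------------------------
# Alternative families
# ---------------------------------------------------------------------------

def scaled_gamma_incidence(a, params: GammaParams):
    """Cumulative incidence ``P * GammaCDF(a; shape, scale)``.

    Uses the lower regularized incomplete Gamma function; with shape 1 it
    reduces to the scaled exponential ``P * (1 - exp(-a/scale))``.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be >= 0")
    out = params.P * special.gammainc(params.shape, a / params.scale)
    return out if out.ndim else float(out)


def power_law_incidence(a, params: PowerLawParams):
    """Classical multistage power law ``c * a**m`` (straight line on log-log axes)."""
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be >= 0")
    out = params.c * a ** params.m
    return out if out.ndim else float(out)
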