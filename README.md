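# weibinc

Multistage models for age-stratified cancer incidence curves.

Age-specific cancer incidence carries a mechanistic signature: if cancer
onset requires a cell lineage to accumulate *k* driver events, each arriving
with small probability *r* per cell division, then the cumulative incidence
curve of a tissue looks like a scaled Weibull distribution function whose
shape parameter estimates *k*. `weibinc` implements that chain of reasoning
as a tested Python package for epidemiological modellers: from the exact
driver-mutation recursion of a single stem-cell lineage, through the
closed-form theoretical lifetime intrinsic risk (tLIR) of a whole tissue, to
practical curve fitting, model comparison, identifiability profiling and
stem-cell-division correlation analyses on registry-style age-incidence
tables.

## The models

A tissue holds `S` stem cells, each dividing `d` times per year after the
`log2(S)` developmental divisions that built the tissue, so a lineage has
passed `n = log2(S) + d·a` divisions by age `a`. With per-division,
per-target mutation probability `r` and `k` required driver events, the
probability that one lineage has collected all `k` hits after `n` divisions
has the closed form

```
P(hit all k) = (1 − (1 − r)^n)^k
```

(equal to the exact division-by-division recursion for integer `n`, and
extending it to real `n` and `k`), and the tissue-level risk is

```
tLIR(a) = 1 − (1 − (1 − (1 − r)^(log2 S + d·a))^k)^S .
```

For `r ≪ 1` and `d·a ≫ log2 S` this 4-parameter curve is approximated by a
scaled Weibull function with 3 parameters,

```
tLIR(a) ≈ P · Weibull(λ, k)(a) = P · (1 − exp(−(a/λ)^k)),
```

with scale fixed by the bridge `S·(r·d)^k = P/λ^k` (so `λ = 1/(r·d)` when
`P = S`). The package fits this scaled Weibull, a scaled Gamma
(`P · GammaCDF(a; shape, scale)`) and the classical multistage power law
(`c·a^m`) to empirical cumulative incidence

```
I(a) = 1 − Π_{i≤a} (1 − p_i),      p_i = per-age diagnosis frequency,
```

scores fits with the squared Pearson correlation `R²` between the empirical
and model curves, and compares families by AIC using a per-age-bin binomial
likelihood when diagnosis counts are available.

## Worked example

Simulate a registry-like cohort (86 one-year age bins, one million people
at risk per bin) from a known scaled-Weibull truth `P = 0.05, λ = 90,
k = 6` — a cancer with a lifetime cumulative incidence of about 2.5% — then
fit and compare all three families:

```python
from weibinc import CohortSpec, WeibullParams, simulate_counts, compare_models

truth = WeibullParams(P=0.05, lambda_=90.0, k=6.0)
series = simulate_counts(CohortSpec(family="weibull", params=truth, seed=11))
table, results = compare_models(series)
print(results["weibull"].summary())
print(table[["rank", "family", "r_squared", "aic"]].to_string(index=False))
```

```
weibull incidence fit (85 age bins)
----------------------------------------------
         P  0.0512268
    lambda  90.5576
         k  5.9885
        R2  0.999978
       SSE  8.38996e-08
    loglik  -258.9355
       AIC  523.8710

 rank   family  r_squared        aic
    1  weibull   0.999978 523.870975
    2    gamma   0.999892 590.904405
    3 powerlaw   0.999203 824.546368
```

The shape estimate `k ≈ 5.99` recovers the number of driver events used to
generate the data, `R² > 0.9999` reproduces the quality of fit seen on real
registry curves, and the generating Weibull family wins the AIC comparison
against the Gamma and the power law. The multiplier `P` and scale `λ` are
individually much softer than `k`: `weibinc.weibull_sensitivity` profiles
the `R² ≥ 0.99` ridge along which both can move by two orders of magnitude
while the refit shape stays within ±1.

The same workflows are available from the shell:

```
weibinc simulate --seed 11 --output-dir demo
weibinc fit --input demo/cohort.csv --families weibull,gamma,powerlaw --output-dir demo
weibinc pipeline --seed 11 --output-dir demo_run
```

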