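"""Cross-day inference: learning-curve linear models, bootstrap
correlation-difference tests, permutation comparisons, FDR correction,
behavior-neural association, and psychometric fits.

Two linear models carry the learning-curve questions: a single-group model

    metric_i = b0 + b1 * day_i + e          (day coded 1, 2, 3, ...)

whose significant positive slope b1 indicates an increase across learning,
and a two-group model with a region x day interaction

    metric_ij = b0 + b1*region_i + b2*day_j + b3*(region_i x day_j) + e

(region = 0 for TEO, 1 for TE) whose interaction term b3 tests for divergent
learning between the regions.

Quantities without repeated measures per day (e.g. a per-day proportion) are
compared between regions by bootstrap-resampling the observations and
forming the distribution of the difference of Pearson correlations against
day. Repeat-level quantities (decoding accuracies) are compared against
their shuffled controls the same way, resampling the repeats within each day
(day labels themselves are never resampled).

Permutation p-values use the add-one convention (b + 1) / (n + 1), so the
resolution floor at n permutations is 1 / (n + 1) and p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests


@dataclass
class LearningFit:
    """OLS fit of a learning-curve model: coefficients, p-values, CIs, ICs."""

    params: dict
    pvalues: dict
    conf_int: dict
    aic: float
    bic: float
    nobs: int

    @property
    def slope(self) -> float:
        return self.params["day"]

    @property
    def slope_p(self) -> float:
        return self.pvalues["day"]


def _ols_fit(y: np.ndarray, X: pd.DataFrame) -> LearningFit:
    model = sm.OLS(y, sm.add_constant(X)).fit()
    names = model.params.index
    ci = model.conf_int()
    return LearningFit(
        params=dict(zip(names, model.params)),
        pvalues=dict(zip(names, model.pvalues)),
        conf_int={n: (float(ci.loc[n, 0]), float(ci.loc[n, 1])) for n in names},
        aic=float(model.aic),
        bic=float(model.bic),
        nobs=int(model.nobs),
    )


def fit_day_lm(metric: Sequence[float], day: Sequence[int]) -> LearningFit:
    """Least-squares fit of metric ~ day (day coded 1, 2, 3, ...)."""
    y = np.asarray(metric, dtype=float)
    d = np.asarray(day, dtype=float)
    if np.unique(d).size < 2:
        raise ValueError("need at least 2 distinct days")
    return _ols_fit(y, pd.DataFrame({"day": d}))


def fit_region_day_interaction(
    metric: Sequence[float], region: Sequence, day: Sequence[int]
) -> LearningFit:
    """Full region x day interaction model; region coded 0 = TEO, 1 = TE.

    The interaction coefficient (key ``"region:day"``) and its p-value carry
    the divergent-learning test.
    """
    y = np.asarray(metric, dtype=float)
    d = np.asarray(day, dtype=float)
    r = np.asarray([x if x in (0, 1) else {"TEO": 0, "TE": 1}[x] for x in region], dtype=float)
    if np.unique(r).size < 2 or np.unique(d).size < 2:
        raise ValueError("need both regions and at least 2 distinct days")
    X = pd.DataFrame({"region": r, "day": d, "region:day": r * d})
    return _ols_fit(y, X)


# ---------------------------------------------------------------------------
# bootstrap / permutation machinery


@dataclass
class BootstrapComparison:
    """Distribution of a bootstrap correlation difference and its CI."""

    n_boot: int
    delta_r: np.ndarray
    ci: tuple[float, float]
    level: float
    sided: str  # "two" or "one"
    significant: bool


def _ci_from_samples(samples: np.ndarray, level: float, sided: str) -> tuple[float, float]:
    if sided == "two":
        alpha = (1.0 - level) / 2.0
        return (
            float(np.quantile(samples, alpha)),
            float(np.quantile(samples, 1.0 - alpha)),
        )
    if sided == "one":
        return (float(np.quantile(samples, 1.0 - level)), np.inf)
    raise ValueError(f"sided must be 'two' or 'one', got {sided!r}")


def _row_corr(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of A with vector b."""
    Ac = A - A.mean(axis=1, keepdims=True)
    bc = b - b.mean()
    denom = np.sqrt((Ac**2).sum(axis=1) * (bc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac @ bc) / denom
    return r


def bootstrap_corr_vs_day(
    values_by_day: Mapping[int, Sequence[float]],
    shuffled_values_by_day: Mapping[int, Sequence[float]],
    n_boot: int = 5000,
    level: float = 0.95,
    sided: str = "two",
    seed: int = 0,
    covariate: Mapping[int, float] | None = None,
) -> BootstrapComparison:
    """Bootstrap test of whether a repeat-level metric correlates with day
    (or with another per-day covariate, e.g. behavioral performance).

    Per bootstrap sample, repeats are resampled with replacement within each
    day and averaged; the Pearson correlation of the day means against day
    number (or the covariate) is computed for the real and the
    shuffled-control metric, and their difference is collected. Significant
    iff the CI excludes 0.
    """
    days = np.array(sorted(values_by_day))
    if days.size < 3:
        raise ValueError("need at least 3 days")
    x = (
        days.astype(float)
        if covariate is None
        else np.array([covariate[d] for d in days], dtype=float)
    )
    rng = np.random.default_rng(seed)

    def boot_means(by_day) -> np.ndarray:
        cols = []
        for d in days:
            v = np.asarray(by_day[d], dtype=float)
            if v.size < 2:
                raise ValueError(f"day {d}: need at least 2 values")
            idx = rng.integers(0, v.size, size=(n_boot, v.size))
            cols.append(v[idx].mean(axis=1))
        return np.column_stack(cols)

    r_real = _row_corr(boot_means(values_by_day), x)
    r_shuf = _row_corr(boot_means(shuffled_values_by_day), x)
    delta = r_real - r_shuf
    delta = delta[~np.isnan(delta)]
    ci = _ci_from_samples(delta, level, sided)
    significant = ci[0] > 0 or ci[1] < 0
    return BootstrapComparison(n_boot, delta, ci, level, sided, bool(significant))


def bootstrap_corr_difference(
    series_a: Sequence[float],
    series_b: Sequence[float],
    covariate: Sequence[float],
    n_boot: int = 5000,
    level: float = 0.95,
    sided: str = "two",
    seed: int = 0,
) -> BootstrapComparison:
    """Bootstrap difference of two Pearson correlations against a common
    covariate, resampling the (paired) observations with replacement.

    Used for metrics with one value per day (e.g. per-day significant-neuron
    proportions in TE vs TEO against day number).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if not a.size == b.size == c.size:
        raise ValueError("series and covariate must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, a.size, size=(n_boot, a.size))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_a = _pairwise_corr(a[idx], c[idx])
        r_b = _pairwise_corr(b[idx], c[idx])
    delta = r_a - r_b
    delta = delta[~np.isnan(delta)]
    ci = _ci_from_samples(delta, level, sided)
    significant = ci[0] > 0 or ci[1] < 0
    return BootstrapComparison(n_boot, delta, ci, level, sided, bool(significant))


def _pairwise_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    denom = np.sqrt((Ac**2).sum(axis=1) * (Bc**2).sum(axis=1))
    return (Ac * Bc).sum(axis=1) / denom


def permutation_compare(
    dist_a: Sequence[float],
    dist_b: Sequence[float],
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for the mean difference of two
    repeat-level distributions (add-one convention)."""
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both distributions must be non-empty")
    obs = abs(a.mean() - b.mean())
    pool = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    n = a.size
    count = 0
    # vectorized: permute the pool n_perm times, split at n
    order = np.argsort(rng.random((n_perm, pool.size)), axis=1)
    perm = pool[order]
    diffs = np.abs(perm[:, :n].mean(axis=1) - perm[:, n:].mean(axis=1))
    count = int(np.sum(diffs >= obs - 1e-12))
    return float((count + 1) / (n_perm + 1))


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# behavior-neural association


def partial_correlation(
    x: Sequence[float], y: Sequence[float], covariates: np.ndarray
) -> tuple[float, float]:
    """Pearson partial correlation of x and y given covariates, with the
    t-transform p-value (df = n - #covariates - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != x.size:
        C = C.T
    n, k = C.shape
    if x.size != y.size or x.size != n:
        raise ValueError("x, y, covariates must share the observation count")
    if n <= k + 2:
        raise ValueError("need n > #covariates + 2 observations")
    D = np.column_stack([np.ones(n), C])
    rx = x - D @ np.linalg.lstsq(D, x, rcond=None)[0]
    ry = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


@dataclass
class BehaviorRegression:
    """Per-predictor-set behavior ~ decoding-accuracy regressions."""

    fits: dict          # predictor set name -> LearningFit
    ic_table: pd.DataFrame  # model, aic, bic
    best_aic: str
    best_bic: str
    interaction_p: dict  # region -> p of accuracy x monkey (if requested)


def behavior_neural_regression(
    behavior: Sequence[float],
    accuracy_te: Sequence[float],
    accuracy_teo: Sequence[float],
    monkey: Sequence,
    with_interaction: bool = False,
) -> BehaviorRegression:
    """Regress behavioral performance on per-day decoding accuracy.

    Fits the three predictor sets {TE}, {TEO}, {TE+TEO}, always with monkey
    identity as a fixed 0/1 covariate, reports per-region slope p-values, and
    ranks the models by AIC and BIC. IC ranking under a fixed model dimension
    is invariant to affine rescaling of the predictors.
    """
    y = np.asarray(behavior, dtype=float)
    te = np.asarray(accuracy_te, dtype=float)
    teo = np.asarray(accuracy_teo, dtype=float)
    mk = np.asarray([m if m in (0, 1) else hash(m) % 2 for m in monkey], dtype=float)
    if np.unique(mk).size == 1:
        mk_cols = {}
    else:
        mk_cols = {"monkey": mk}
    designs = {
        "TE": pd.DataFrame({"accuracy_TE": te, **mk_cols}),
        "TEO": pd.DataFrame({"accuracy_TEO": teo, **mk_cols}),
        "TE+TEO": pd.DataFrame({"accuracy_TE": te, "accuracy_TEO": teo, **mk_cols}),
    }
    fits = {name: _ols_fit(y, X) for name, X in designs.items()}
    ic = pd.DataFrame(
        [(name, f.aic, f.bic) for name, f in fits.items()],
        columns=["model", "aic", "bic"],
    )
    interaction_p = {}
    if with_interaction and mk_cols:
        for name, acc in (("TE", te), ("TEO", teo)):
            X = pd.DataFrame({"acc": acc, "monkey": mk, "acc:monkey": acc * mk})
            interaction_p[name] = _ols_fit(y, X).pvalues["acc:monkey"]
    return BehaviorRegression(
        fits=fits,
        ic_table=ic,
        best_aic=str(ic.loc[ic["aic"].idxmin(), "model"]),
        best_bic=str(ic.loc[ic["bic"].idxmin(), "model"]),
        interaction_p=interaction_p,
    )


# ---------------------------------------------------------------------------
# psychometrics


@dataclass
class PsychometricFit:
    slope: float
    bias: float
    nll: float
    at_cap: bool


def fit_psychometric(
    morph_levels: Sequence[int],
    second_choice: Sequence[bool],
    slope_cap: float = 50.0,
) -> PsychometricFit:
    """Maximum-likelihood 2-parameter logistic psychometric fit.

    Models P(second-interval release, i.e. "dog" report) as
    logistic(slope * (level - 50)/50 + bias). The slope is capped for
    separable (step-function) data, where the ML slope diverges.
    """
    lv = np.asarray(morph_levels, dtype=float)
    y = np.asarray(second_choice, dtype=float)
    if np.unique(lv).size < 3:
        raise ValueError("need choices at >= 3 morph levels")
    x = (lv - 50.0) / 50.0

    def nll(theta):
        z = theta[0] * x + theta[1]
        return float(np.sum(np.logaddexp(0.0, z) - y * z))

    best = None
    for s0 in (0.5, 2.0, 8.0):
        res = optimize.minimize(
            nll, x0=np.array([s0, 0.0]), method="L-BFGS-B",
            bounds=[(-slope_cap, slope_cap), (-20.0, 20.0)],
        )
        if best is None or res.fun < best.fun:
            best = res
    slope, bias = best.x
    return PsychometricFit(
        slope=float(slope),
        bias=float(bias),
        nll=float(best.fun),
        at_cap=bool(abs(abs(slope) - slope_cap) < 1e-6),
    )
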