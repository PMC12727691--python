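import numpy as np
import pytest
from itertools import combinations

import catmorph as cm
from catmorph.learning_stats import (
    behavior_neural_regression,
    bh_fdr,
    bootstrap_corr_difference,
    bootstrap_corr_vs_day,
    fit_day_lm,
    fit_psychometric,
    fit_region_day_interaction,
    partial_correlation,
    permutation_compare,
)

# ---------------------------------------------------------------------------
# linear models


def test_fit_day_lm_exact_line():
    days = [1, 2, 3, 4, 5]
    fit = fit_day_lm([2 * d for d in days], days)
    assert fit.slope == pytest.approx(2.0)
    assert fit.params["const"] == pytest.approx(0.0, abs=1e-10)


def test_fit_day_lm_matches_normal_equations():
    days = np.array([1, 1, 2, 2, 3, 3])
    y = np.array([0.3, 0.5, 0.9, 0.7, 1.4, 1.2])
    X = np.column_stack([np.ones(6), days])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    fit = fit_day_lm(y, days)
    assert fit.params["const"] == pytest.approx(beta[0])
    assert fit.slope == pytest.approx(beta[1])
    with pytest.raises(ValueError):
        fit_day_lm([1.0, 2.0], [3, 3])


def test_interaction_model_recovers_divergent_slopes():
    rng = np.random.default_rng(0)
    days = np.tile(np.arange(1, 6), 40)
    region = np.repeat(["TE", "TEO"], 100)
    slope = np.where(region == "TE", 1.0, 0.0)
    y = 0.5 + slope * days + rng.normal(0, 0.3, 200)
    fit = fit_region_day_interaction(y, region, days)
    # region coding: TE = 1, so the interaction coefficient is the slope gap
    assert fit.params["region:day"] == pytest.approx(1.0, abs=0.15)
    assert fit.pvalues["region:day"] < 1e-6
    ci = fit.conf_int["region:day"]
    assert ci[0] < 1.0 < ci[1]


def test_interaction_model_null_calibration():
    rng = np.random.default_rng(1)
    hits = 0
    for i in range(400):
        days = np.tile(np.arange(1, 6), 8)
        region = np.repeat(["TE", "TEO"], 20)
        y = rng.normal(size=40)
        fit = fit_region_day_interaction(y, region, days)
        hits += fit.pvalues["region:day"] < 0.05
    assert 0.02 < hits / 400 < 0.09  # binomial range around the nominal 5%


# ---------------------------------------------------------------------------
# bootstrap comparisons


def _by_day(arrs):
    return {d + 1: np.asarray(v, dtype=float) for d, v in enumerate(arrs)}


def test_bootstrap_corr_vs_day_detects_increase():
    rng = np.random.default_rng(0)
    real = _by_day([0.55 + 0.05 * d + 0.02 * rng.normal(size=20) for d in range(5)])
    shuf = _by_day([0.5 + 0.02 * rng.normal(size=20) for _ in range(5)])
    b = bootstrap_corr_vs_day(real, shuf, n_boot=1000, seed=0)
    assert b.significant and np.mean(b.delta_r) > 0
    b2 = bootstrap_corr_vs_day(real, shuf, n_boot=1000, seed=0)
    assert np.array_equal(b.delta_r, b2.delta_r)  # deterministic under seed


def test_bootstrap_corr_vs_day_input_checks():
    rng = np.random.default_rng(0)
    two_days = _by_day([rng.normal(size=5)] * 2)
    with pytest.raises(ValueError, match="3 days"):
        bootstrap_corr_vs_day(two_days, two_days)


def test_bootstrap_corr_difference_identical_series_centered_at_zero():
    a = np.array([0.2, 0.4, 0.5, 0.7, 0.9])
    b = bootstrap_corr_difference(a, a.copy(), [1, 2, 3, 4, 5], n_boot=500, seed=0)
    assert not b.significant
    assert np.allclose(b.delta_r, 0.0)


def test_bootstrap_corr_difference_opposite_trends_one_sided():
    a = np.array([0.1, 0.3, 0.5, 0.7, 0.9, 0.95])
    b = np.array([0.9, 0.7, 0.5, 0.45, 0.2, 0.1])
    res = bootstrap_corr_difference(a, b, np.arange(1, 7), n_boot=500, sided="one", seed=1)
    assert res.ci[0] > 0 and res.ci[1] == np.inf and res.significant


# ---------------------------------------------------------------------------
# permutation & FDR


def test_permutation_compare_identical_data_p_is_one():
    a = np.array([1.0, 2.0, 3.0])
    assert permutation_compare(a, a.copy(), n_perm=200, seed=0) == pytest.approx(1.0)


def test_permutation_compare_disjoint_hits_resolution_floor():
    # large disjoint samples: the observed split is essentially never redrawn,
    # so p sits at the add-one floor
    a = np.arange(100.0, 108.0)
    b = np.arange(0.0, 8.0)
    p = permutation_compare(a, b, n_perm=999, seed=0)
    assert p <= 2 / (999 + 1)


def test_permutation_compare_matches_exhaustive_enumeration():
    a = np.array([3.1, 4.0, 5.2])
    b = np.array([2.0, 2.5, 4.8])
    obs = abs(a.mean() - b.mean())
    pool = np.r_[a, b]
    count = 0
    for idx in combinations(range(6), 3):
        rest = [i for i in range(6) if i not in idx]
        count += abs(pool[list(idx)].mean() - pool[rest].mean()) >= obs - 1e-12
    exact = count / 20
    approx = permutation_compare(a, b, n_perm=4000, seed=3)
    assert approx == pytest.approx(exact, abs=0.05)


def brute_force_bh(p):
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def test_bh_fdr_step_up_examples():
    assert bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05]) == pytest.approx([0.05] * 5)
    assert bh_fdr([0.42]) == pytest.approx([0.42])
    assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


def test_bh_fdr_matches_brute_force_with_invariants():
    rng = np.random.default_rng(0)
    for _ in range(50):
        p = rng.random(rng.integers(1, 12))
        adj = bh_fdr(p)
        assert adj == pytest.approx(brute_force_bh(p), abs=1e-12)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        # monotone after sorting by raw p
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# partial correlation / behavior regression


def test_partial_correlation_limiting_cases():
    rng = np.random.default_rng(0)
    x = rng.normal(size=30)
    z = rng.normal(size=30)
    r, p = partial_correlation(x, x * 2 + 1, z)
    assert r == pytest.approx(1.0) and p == 0.0
    y = 3 * z + 1e-9 * rng.normal(size=30)
    r2, p2 = partial_correlation(x, y, z)
    assert abs(r2) < 0.2


def test_partial_correlation_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(2)
    df = pd.DataFrame(
        {"x": rng.normal(size=10), "y": rng.normal(size=10), "c": rng.normal(size=10)}
    )
    df["y"] += 0.7 * df["x"]
    ours_r, ours_p = partial_correlation(df["x"], df["y"], df[["c"]].to_numpy())
    ref = pingouin.partial_corr(df, x="x", y="y", covar="c")
    assert ours_r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
    assert ours_p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)


def test_behavior_regression_prefers_predictive_region():
    rng = np.random.default_rng(4)
    wins = 0
    for i in range(20):
        te = rng.uniform(0.5, 0.9, 10)
        teo = rng.uniform(0.5, 0.9, 10)
        monkey = np.r_[np.zeros(5), np.ones(5)]
        behavior = 0.2 + 0.8 * te + rng.normal(0, 0.03, 10)
        res = behavior_neural_regression(behavior, te, teo, monkey)
        wins += res.best_aic == "TE"
        assert res.fits["TE"].pvalues["accuracy_TE"] < 0.05 or i > 0
    assert wins >= 14


def test_behavior_regression_ic_ranking_affine_invariant():
    rng = np.random.default_rng(5)
    te = rng.uniform(0.5, 0.9, 12)
    teo = rng.uniform(0.5, 0.9, 12)
    monkey = np.r_[np.zeros(6), np.ones(6)]
    behavior = 0.3 + 0.6 * te + rng.normal(0, 0.02, 12)
    a = behavior_neural_regression(behavior, te, teo, monkey)
    b = behavior_neural_regression(behavior, te * 100 - 3, teo * 100 - 3, monkey)
    assert a.best_aic == b.best_aic and a.best_bic == b.best_bic


def test_behavior_regression_interaction_term():
    rng = np.random.default_rng(6)
    te = rng.uniform(0.5, 0.9, 12)
    teo = rng.uniform(0.5, 0.9, 12)
    monkey = np.r_[np.zeros(6), np.ones(6)]
    behavior = 0.3 + 0.6 * te + rng.normal(0, 0.02, 12)
    res = behavior_neural_regression(behavior, te, teo, monkey, with_interaction=True)
    assert set(res.interaction_p) == {"TE", "TEO"}


# ---------------------------------------------------------------------------
# psychometrics


def test_psychometric_step_function_hits_cap():
    levels = [0, 25, 45, 55, 75, 100] * 20
    choices = [l > 50 for l in levels]
    fit = fit_psychometric(levels, choices, slope_cap=50.0)
    assert fit.at_cap and fit.slope == pytest.approx(50.0)


def test_psychometric_flat_choices_give_zero_slope():
    rng = np.random.default_rng(0)
    levels = np.repeat([0, 25, 45, 55, 75, 100], 200)
    choices = rng.random(levels.size) < 0.5
    fit = fit_psychometric(levels, choices)
    assert abs(fit.slope) < 0.3 and not fit.at_cap


def test_psychometric_recovers_generator_parameters():
    exp = cm.ExperimentConfig(n_identities=10, days=1, seed=0)
    cfg = cm.GeneratorConfig(
        experiment=exp, n_neurons={"TE": 2, "TEO": 2},
        repeats_per_image=(12, 12), psychometric_slope=2.0,
        psychometric_bias=0.5, seed=8,
    )
    s = cm.simulate_session(cfg, 1)
    levels = [t.image.morph_level for t in s.trials]
    second = [t.choice == "second_interval" for t in s.trials]
    assert len(levels) >= 100 * 11  # >= 100 trials per level
    fit = fit_psychometric(levels, second)
    assert fit.slope == pytest.approx(2.0, abs=0.25)
    assert fit.bias == pytest.approx(0.5, abs=0.15)
    with pytest.raises(ValueError):
        fit_psychometric([0, 100], [False, True])
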