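import numpy as np
import pytest
from dataclasses import replace
from sklearn.base import clone

import catmorph as cm
from catmorph.core_io import StimulusImage
from catmorph.decoding import (
    DecoderSpec,
    SigmoidDecoder,
    SplitSpec,
    decode_choice,
    decode_correct_vs_error,
    decode_generalization,
    decode_traditional,
    correct_error_image_filter,
    identity_folds,
    shuffled_control,
    train_decoder,
    zscore_per_neuron,
)

# ---------------------------------------------------------------------------
# z-scoring


def test_zscore_closed_form():
    Z = zscore_per_neuron(np.array([[1.0], [2.0], [3.0]]))
    assert Z.ravel() == pytest.approx([-1.0, 0.0, 1.0], abs=1e-6)  # SD with n-1 = 1.0
    Z2 = zscore_per_neuron(np.array([[1.0, 5.0], [2.0, 5.0], [4.0, 5.0]]))
    assert Z2[:, 0].mean() == pytest.approx(0.0, abs=1e-12)
    assert Z2[:, 0].std(ddof=1) == pytest.approx(1.0)


def test_zscore_constant_column_warns_and_zeroes():
    with pytest.warns(UserWarning, match="constant"):
        Z = zscore_per_neuron(np.array([[1.0, 7.0], [2.0, 7.0]]))
    assert np.all(Z[:, 1] == 0)


def test_zscore_idempotent():
    rng = np.random.default_rng(0)
    X = rng.normal(3, 2, size=(20, 4))
    once = zscore_per_neuron(X)
    assert zscore_per_neuron(once) == pytest.approx(once, abs=1e-10)


def test_zscore_train_only_scope():
    X = np.array([[0.0], [1.0], [2.0], [100.0]])
    Z = zscore_per_neuron(X, fit_rows=np.array([0, 1, 2]))
    assert Z[:3].mean() == pytest.approx(0.0, abs=1e-12)
    assert Z[3, 0] > 10  # test row is scaled by train moments only


# ---------------------------------------------------------------------------
# decoder contract


def _toy_separable(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = np.r_[rng.normal(-2, 0.3, (n // 2, 2)), rng.normal(2, 0.3, (n // 2, 2))]
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
    return X, y


def test_decoder_fits_separable_toy_data():
    X, y = _toy_separable()
    dec = SigmoidDecoder(random_state=0).fit(X, y)
    assert (dec.predict(X) == y).all()
    assert dec.stop_reason_ in ("gradient", "max_epochs", "patience")


def test_decoder_is_deterministic_given_seed():
    X, y = _toy_separable()
    a = SigmoidDecoder(random_state=5).fit(X, y)
    b = SigmoidDecoder(random_state=5).fit(X, y)
    assert np.array_equal(a.coef_, b.coef_) and a.n_epochs_ == b.n_epochs_


def test_decoder_patience_returns_minimum_validation_weights():
    rng = np.random.default_rng(1)
    # weak signal + tiny validation set: validation error rises quickly
    X = rng.normal(size=(60, 30))
    y = (rng.random(60) < 0.5).astype(int)
    Xv, yv = rng.normal(size=(8, 30)), (rng.random(8) < 0.5).astype(int)
    dec = SigmoidDecoder(random_state=0, patience=6).fit(X, y, validation=(Xv, yv))
    assert dec.stop_reason_ == "patience"
    trace = np.array(dec.val_error_trace_)
    # the run of rising validation errors at the stop is exactly the patience
    rising = 0
    for a, b in zip(trace[:-1], trace[1:]):
        rising = rising + 1 if b > a else 0
    assert rising == 6
    # returned weights achieve the minimum validation error seen
    zv = Xv @ dec.coef_.ravel() + dec.intercept_[0]
    err = float(np.mean(np.logaddexp(0.0, zv) - yv * zv))
    assert err == pytest.approx(trace.min(), abs=1e-10)


def test_decoder_gradient_stop_on_easy_problem():
    X = np.array([[-1.0], [1.0]] * 10)
    y = np.array([0, 1] * 10)
    dec = SigmoidDecoder(random_state=0, max_epochs=200_000, gradient_tol=1e-4).fit(X, y)
    assert dec.stop_reason_ in ("gradient", "max_epochs")


def test_decoder_rejects_single_class_and_supports_clone():
    X, y = _toy_separable()
    with pytest.raises(ValueError):
        SigmoidDecoder().fit(X, np.zeros_like(y))
    dec = SigmoidDecoder(patience=3, random_state=1)
    c = clone(dec)
    assert c.get_params()["patience"] == 3
    proba = dec.fit(X, y).predict_proba(X)
    assert proba.shape == (len(y), 2)
    assert np.allclose(proba.sum(axis=1), 1.0)


def test_train_decoder_wrapper_respects_spec():
    X, y = _toy_separable()
    spec = DecoderSpec(max_epochs=7)
    dec = train_decoder((X, y), None, spec, seed=0)
    assert dec.n_epochs_ <= 7


# ---------------------------------------------------------------------------
# split strategies


@pytest.fixture(scope="module")
def strong_session():
    exp = cm.ExperimentConfig(n_identities=4, days=1, seed=0)
    cfg = cm.GeneratorConfig(
        experiment=exp,
        n_neurons={"TE": 24, "TEO": 16},
        category_gain={"TE": (2.5, 0.0), "TEO": (0.0, 0.0)},
        shared_axis_fraction=1.0,
        repeats_per_image=(6, 6),
        seed=3,
    )
    return cm.simulate_session(cfg, 1)


@pytest.fixture(scope="module")
def null_session():
    cfg = cm.null_config(seed=4)
    cfg = replace(
        cfg,
        experiment=replace(cfg.experiment, n_identities=4),
        n_neurons={"TE": 24, "TEO": 16},
        repeats_per_image=(6, 6),
    )
    return cm.simulate_session(cfg, 1)


SMALL = SplitSpec(trials_per_image=6, n_train=4, n_val=1, n_test=1, n_neurons=16, n_repeats=8)


def test_traditional_decoding_strong_signal(strong_session):
    res = decode_traditional(strong_session, "TE", SMALL, seed=0, with_shuffle=False)
    assert res.accuracies.mean() > 0.9


def test_traditional_decoding_null_session(null_session):
    res = decode_traditional(null_session, "TE", SMALL, seed=0)
    band = 3 * res.shuffled_accuracies.std(ddof=1) / np.sqrt(len(res.shuffled_accuracies))
    assert abs(res.accuracies.mean() - res.shuffled_accuracies.mean()) < max(band, 0.06)


def test_traditional_decoding_deterministic(strong_session):
    one = SplitSpec(6, 4, 1, 1, 8, 1)
    a = decode_traditional(strong_session, "TE", one, seed=9)
    b = decode_traditional(strong_session, "TE", one, seed=9)
    assert np.array_equal(a.accuracies, b.accuracies)
    assert np.array_equal(a.scores[0][0], b.scores[0][0])
    assert np.array_equal(a.shuffled_accuracies, b.shuffled_accuracies)


def test_traditional_split_geometry(strong_session):
    res = decode_traditional(
        strong_session, "TE", SplitSpec(6, 4, 1, 1, 8, 3), seed=1, record_splits=True
    )
    n_images = 4 * 10  # identities x non-boundary levels
    for sp in res.extra["splits"]:
        tr, va, te = sp["train"], sp["val"], sp["test"]
        assert len(tr) == 4 * n_images and len(va) == n_images and len(te) == n_images
        assert not (set(te) & set(tr)) and not (set(te) & set(va)) and not (set(tr) & set(va))
        assert len(sp["columns"]) == 8


def test_traditional_errors_on_insufficient_trials(strong_session):
    big = SplitSpec(trials_per_image=50, n_train=48, n_val=1, n_test=1, n_neurons=8, n_repeats=1)
    with pytest.raises(ValueError, match="fewer than 50"):
        decode_traditional(strong_session, "TE", big, seed=0)
    with pytest.raises(ValueError, match="n_train"):
        decode_traditional(strong_session, "TE", SplitSpec(6, 3, 1, 1, 8, 1), seed=0)


def test_identity_folds_partition():
    rng = np.random.default_rng(0)
    folds = identity_folds([1, 2, 3, 4, 5, 6], 3, rng)
    got = sorted(np.concatenate(folds).tolist())
    assert got == [1, 2, 3, 4, 5, 6]
    with pytest.raises(ValueError):
        identity_folds([1, 2], 3, rng)


def test_generalization_tests_only_heldout_identities(strong_session):
    split = SplitSpec(trials_per_image=6, n_train=5, n_val=1, n_test=0,
                      n_neurons=8, n_repeats=2, n_folds=2)
    res = decode_generalization(strong_session, "TE", split, seed=0,
                                record_splits=True, with_shuffle=False)
    meta_ident = np.array(
        [t.image.morph_identity for t in strong_session.trials if t.image.category != "boundary"]
    )
    tested = {r: [] for r in range(2)}
    for sp in res.extra["splits"]:
        train_ids = set(meta_ident[sp["train"]])
        test_ids = set(meta_ident[sp["test"]])
        assert not (train_ids & test_ids)  # no held-out identity in training
        assert test_ids == set(sp["fold"])
        tested[sp["repeat"]].extend(test_ids)
    for r in range(2):  # each identity tested exactly once per CV pass
        assert sorted(tested[r]) == [1, 2, 3, 4]


def test_shuffled_control_pairs_draws_and_destroys_signal(strong_session):
    res = decode_traditional(strong_session, "TE", SMALL, seed=2)
    # paired draws: shuffled run exists for every repeat, same repeat count
    assert len(res.shuffled_accuracies) == len(res.accuracies)
    # destroyed signal
    assert abs(res.shuffled_accuracies.mean() - 0.5) < 0.15
    assert res.accuracies.mean() - res.shuffled_accuracies.mean() > 0.2
    flipped = shuffled_control(decode_traditional, strong_session, "TE", SMALL, seed=2)
    assert np.array_equal(flipped.accuracies, res.shuffled_accuracies)


def test_combined_region_pools_equal_counts(strong_session):
    res = decode_traditional(
        strong_session, ("TE", "TEO"), SplitSpec(6, 4, 1, 1, 8, 2),
        seed=0, record_splits=True, with_shuffle=False,
    )
    assert len(res.extra["splits"][0]["columns"]) == 16  # 8 from each region


# ---------------------------------------------------------------------------
# choice decoding


def test_choice_decoding_detects_choice_coupling():
    exp = cm.ExperimentConfig(n_identities=4, days=1, seed=0)
    base = dict(
        experiment=exp, n_neurons={"TE": 20, "TEO": 4},
        category_gain={"TE": (0.0, 0.0), "TEO": (0.0, 0.0)},
        repeats_per_image=(30, 30), psychometric_slope=0.0, seed=6,
    )
    coupled = cm.GeneratorConfig(**base, choice_coupling=3.0)
    uncoupled = cm.GeneratorConfig(**base, choice_coupling=0.0)
    split = SplitSpec(n_neurons=12, n_repeats=10)
    s1 = cm.simulate_session(coupled, 1)
    r1 = decode_choice(s1, "TE", split, seed=0)
    assert r1.accuracies.mean() - r1.shuffled_accuracies.mean() > 0.15
    s0 = cm.simulate_session(uncoupled, 1)
    r0 = decode_choice(s0, "TE", split, seed=0)
    assert abs(r0.accuracies.mean() - r0.shuffled_accuracies.mean()) < 0.12
    # determinism
    r1b = decode_choice(s1, "TE", split, seed=0)
    assert np.array_equal(r1.accuracies, r1b.accuracies)


def test_choice_decoding_requires_both_choices(strong_session):
    s = cm.simulate_session(
        cm.GeneratorConfig(
            experiment=cm.ExperimentConfig(n_identities=2, days=1, seed=0),
            n_neurons={"TE": 4, "TEO": 2}, psychometric_slope=0.0,
            psychometric_bias=50.0, repeats_per_image=(6, 6), seed=0,
        ),
        1,
    )
    with pytest.raises(ValueError, match="both choices"):
        decode_choice(s, "TE", SplitSpec(n_neurons=2, n_repeats=1), seed=0)


# ---------------------------------------------------------------------------
# correct vs error


def _ce_config(**over):
    exp = cm.ExperimentConfig(n_identities=4, days=2, seed=0)
    base = dict(
        experiment=exp,
        n_neurons={"TE": 24, "TEO": 4},
        category_gain={"TE": (2.0, 0.0), "TEO": (0.0, 0.0)},
        shared_axis_fraction=1.0,
        repeats_per_image=(12, 12),
        psychometric_slope=2.0,
        seed=11,
    )
    base.update(over)
    return cm.GeneratorConfig(**base)


def test_correct_error_filter_rules():
    cfg = _ce_config(psychometric_slope=4.0)  # ~80% performance, above threshold
    sessions = [cm.simulate_session(cfg, d) for d in (1, 2)]
    # force day 1 below threshold: flip most outcomes
    for t in sessions[0].trials:
        if t.outcome == "correct":
            t.outcome = "error"
    ledger = correct_error_image_filter(sessions, min_correct=3)
    assert ledger["skipped_days"] == [1]
    # deplete one training image's correct trials on the qualifying day
    removed = 0
    key = (1, 0)
    for t in sessions[1].trials:
        if (t.image.morph_identity, t.image.morph_level) == key and t.outcome == "correct" and removed < 20:
            t.outcome = "error"
            removed += 1
    ledger2 = correct_error_image_filter(sessions, min_correct=3)
    excl = ledger2["excluded_train_images"]
    assert "(1, 0)" in excl
    assert "(1, 100)" in excl and "partner" in excl["(1, 100)"]


def test_correct_error_decoding_reflects_weaker_error_signal():
    cfg = _ce_config(error_signal_attenuation=0.0, psychometric_slope=1.2)
    sessions = [cm.simulate_session(cfg, d) for d in (1, 2)]
    split = SplitSpec(n_neurons=16, n_repeats=10)
    res = decode_correct_vs_error(
        sessions, "TE", split, min_correct=3, performance_threshold=0.5, seed=0
    )
    diffs = []
    for day, (rc, re_) in res.per_day.items():
        diffs.append(rc.accuracies.mean() - re_.accuracies.mean())
    assert np.mean(diffs) > 0.1


def test_correct_error_requires_qualifying_days():
    cfg = _ce_config(psychometric_slope=0.2)  # ~55% performance
    sessions = [cm.simulate_session(cfg, d) for d in (1, 2)]
    with pytest.raises(ValueError):
        decode_correct_vs_error(sessions, "TE", SplitSpec(n_neurons=8, n_repeats=2),
                                min_correct=3, performance_threshold=0.9, seed=0)
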