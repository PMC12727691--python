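"""Population category, generalization, choice, and correct-vs-error
decoding.

The decoder is a single linear unit with sigmoid output trained on
cross-entropy loss by full-batch gradient descent with an adaptive step
size. Training halts on whichever fires first: (1) validation error rising
for 6 consecutive epochs (the weights at minimum validation error are then
returned), (2) gradient norm below 1e-7, or (3) 10,000 epochs. The decoder
is a scikit-learn estimator (:class:`SigmoidDecoder`) and composes with
sklearn pipelines and model selection.

Split geometry, per strategy:

``traditional``
    per non-boundary image, ``trials_per_image`` randomly drawn trials are
    split train / validation / test (e.g. 4/1/1 of 6); fresh neuron
    subsample and trial draw per repeat.
``generalization``
    folds partition *morph identities*; the decoder trains on images of the
    in-fold identities (per image, train + validation trials) and is tested
    only on trials of images from held-out identities it has never seen.
``choice``
    boundary-image trials grouped by the animal's choice and split
    80/10/10 per group.
``correct_error``
    one decoder trained on correct trials of low-ambiguity images (morph
    level 0/25/75/100), tested separately on correct and error trials of
    ambiguous images (35-65%), with the day/image qualification rules
    applied and an exclusion ledger emitted.

Shuffled controls reuse the paired run's neuron subsamples and trial draws
exactly and permute training labels only (in the generalization variant the
validation labels are shuffled as well; test labels are never touched).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .core_io import (
    BOUNDARY,
    DOG,
    SessionData,
    behavioral_correct_rate,
    build_population_matrix,
)

AMBIGUOUS_LEVELS = (35, 40, 45, 55, 60, 65)
LOW_AMBIGUITY_LEVELS = (0, 25, 75, 100)
_PARTNER_LEVEL = {0: 100, 100: 0, 25: 75, 75: 25}


def zscore_per_neuron(
    matrix: np.ndarray, fit_rows: np.ndarray | None = None
) -> np.ndarray:
    """Z-score each column (neuron) to mean 0, SD 1 (SD normalized by n-1).

    ``fit_rows`` optionally restricts the rows used to estimate mean and SD
    (the leakage-free variant fits them on training rows only). Constant
    columns come back as zeros with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    ref = X if fit_rows is None else X[fit_rows]
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} constant neuron column(s) z-scored to zeros")
        sd = np.where(flat, 1.0, sd)
    out = (X - mu) / sd
    out[:, flat] = 0.0
    return out


@dataclass
class DecoderSpec:
    """Training contract of the decoder: one sigmoid unit, cross-entropy,
    and the three stopping rules."""

    patience: int = 6
    gradient_tol: float = 1e-7
    max_epochs: int = 10_000
    learning_rate: float = 1.0
    zscore_scope: str = "all"  # "all" (default) or "train" (leakage-free)


class SigmoidDecoder(ClassifierMixin, BaseEstimator):
    """One-layer, one-unit sigmoid network trained on cross-entropy.

    Full-batch gradient descent with a bold-driver adaptive step (the step
    grows 5% after an accepted epoch and is halved, with the step undone,
    after a rejected one -- deterministic given ``random_state``). Early
    stopping follows the validation-patience / gradient / epoch-cap
    contract described in the module docstring.

    Attributes set by :meth:`fit`: ``coef_``, ``intercept_``, ``classes_``,
    ``n_epochs_``, ``stop_reason_`` ("patience", "gradient" or
    "max_epochs"), ``loss_trace_``, ``val_error_trace_``.
    """

    def __init__(
        self,
        patience: int = 6,
        gradient_tol: float = 1e-7,
        max_epochs: int = 10_000,
        learning_rate: float = 1.0,
        init_scale: float = 0.01,
        random_state: int | None = None,
    ):
        self.patience = patience
        self.gradient_tol = gradient_tol
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.init_scale = init_scale
        self.random_state = random_state

    @staticmethod
    def _loss(z: np.ndarray, y: np.ndarray) -> float:
        # mean cross-entropy via logaddexp for stability
        return float(np.mean(np.logaddexp(0.0, z) - y * z))

    def fit(self, X, y, validation: tuple[np.ndarray, np.ndarray] | None = None):
        X, y = check_X_y(X, y)
        self.classes_, y01 = np.unique(y, return_inverse=True)
        if self.classes_.size != 2:
            raise ValueError(f"exactly 2 classes required, got {self.classes_.size}")
        y01 = y01.astype(float)
        n, p = X.shape
        rng = np.random.default_rng(self.random_state)
        w = rng.normal(0.0, self.init_scale, size=p + 1)
        Xb = np.column_stack([X, np.ones(n)])
        if validation is not None:
            Xv, yv = validation
            Xv = np.asarray(Xv, dtype=float)
            yv01 = (np.asarray(yv) == self.classes_[1]).astype(float)
            Xvb = np.column_stack([Xv, np.ones(len(Xv))])

        lr = float(self.learning_rate)
        z = Xb @ w
        loss = self._loss(z, y01)
        best_val = np.inf
        best_w = w.copy()
        rising = 0
        prev_val = np.inf
        self.loss_trace_ = [loss]
        self.val_error_trace_ = []
        stop = "max_epochs"
        epoch = 0
        while epoch < self.max_epochs:
            epoch += 1
            prob = 1.0 / (1.0 + np.exp(-z))
            grad = Xb.T @ (prob - y01) / n
            gnorm = float(np.linalg.norm(grad))
            if gnorm < self.gradient_tol:
                stop = "gradient"
                break
            w_new = w - lr * grad
            z_new = Xb @ w_new
            loss_new = self._loss(z_new, y01)
            if loss_new > loss:
                lr *= 0.5  # reject the step
                continue
            w, z, loss = w_new, z_new, loss_new
            lr *= 1.05
            self.loss_trace_.append(loss)
            if validation is not None:
                val_err = self._loss(Xvb @ w, yv01)
                self.val_error_trace_.append(val_err)
                if val_err < best_val:
                    best_val = val_err
                    best_w = w.copy()
                rising = rising + 1 if val_err > prev_val else 0
                prev_val = val_err
                if rising >= self.patience:
                    stop = "patience"
                    w = best_w  # weights at minimum validation error
                    break
        self.n_epochs_ = epoch
        self.stop_reason_ = stop
        self.coef_ = w[:-1].reshape(1, -1)
        self.intercept_ = w[-1:].copy()
        return self

    def decision_function(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return X @ self.coef_.ravel() + self.intercept_[0]

    def predict_proba(self, X):
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) >= 0.0).astype(int)]


def train_decoder(
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray] | None,
    spec: DecoderSpec | None = None,
    seed: int | None = 0,
) -> SigmoidDecoder:
    """Fit a :class:`SigmoidDecoder` under ``spec``; deterministic given seed."""
    spec = spec or DecoderSpec()
    dec = SigmoidDecoder(
        patience=spec.patience,
        gradient_tol=spec.gradient_tol,
        max_epochs=spec.max_epochs,
        learning_rate=spec.learning_rate,
        random_state=seed,
    )
    X, y = train
    return dec.fit(X, y, validation=val)


# ---------------------------------------------------------------------------
# split machinery


@dataclass
class SplitSpec:
    """Trial/neuron sampling sizes for one decoding run.

    Defaults follow the monkey-T design: 6 trials per image split 4/1/1
    (traditional) or 5/1 + held-out-identity test (generalization), an
    8-neuron subsample, 100 repeats, 10 identity folds.
    """

    trials_per_image: int = 6
    n_train: int = 4
    n_val: int = 1
    n_test: int = 1
    n_neurons: int = 8
    n_repeats: int = 100
    n_folds: int = 10


MONKEY_T_SPLIT = SplitSpec()
MONKEY_X_SPLIT = SplitSpec(trials_per_image=9, n_train=7, n_val=1, n_test=1,
                           n_neurons=59, n_folds=10)


@dataclass
class DecodingResult:
    """Per-repeat accuracies and test-trial decoder scores, with the paired
    shuffled control (identical draws, permuted training labels)."""

    strategy: str
    region: str | tuple
    n_neurons: int
    seed: int
    accuracies: np.ndarray
    scores: list  # per repeat: (sigmoid scores, true 0/1 labels with 1 = dog)
    shuffled_accuracies: np.ndarray | None = None
    shuffled_scores: list | None = None
    extra: dict = field(default_factory=dict)


def _image_groups(meta: pd.DataFrame) -> dict[tuple[int, int], np.ndarray]:
    key = list(zip(meta["morph_identity"], meta["morph_level"]))
    groups: dict[tuple[int, int], list[int]] = {}
    for row, k in enumerate(key):
        groups.setdefault(k, []).append(row)
    return {k: np.array(v) for k, v in groups.items()}



def _column_regions(session: SessionData, ids) -> list[str]:
    """Region of each population-matrix column, in column order."""
    lut = {n.neuron_id: n.region for n in session.neurons}
    return [lut[i] for i in ids]

def _subsample_columns(
    session: SessionData, region, n_neurons: int, rng: np.random.Generator,
    neuron_regions: Sequence[str],
) -> np.ndarray:
    """Neuron-column subsample: ``n_neurons`` per region (pooled regions
    each contribute the same number, per the combined-ensemble rule)."""
    regions = (region,) if isinstance(region, str) else tuple(region)
    reg = np.asarray(neuron_regions)
    cols = []
    for r in regions:
        avail = np.flatnonzero(reg == r)
        if avail.size < n_neurons:
            raise ValueError(
                f"region {r} has {avail.size} neurons, need {n_neurons}"
            )
        cols.append(rng.choice(avail, size=n_neurons, replace=False))
    return np.concatenate(cols)


def _accuracy_and_scores(dec: SigmoidDecoder, X, y01):
    p = dec.predict_proba(X)[:, 1]
    acc = float(np.mean((p >= 0.5).astype(int) == y01))
    return acc, (p, np.asarray(y01, dtype=int))


def _zscore_for_repeat(mat, rows_used, train_rows, scope):
    """Z-score the repeat's trial draw; scope 'all' uses every drawn trial,
    'train' fits the moments on training rows only (leakage-free)."""
    sub = mat[rows_used]
    if scope == "train":
        pos = {r: i for i, r in enumerate(rows_used)}
        fit = np.array([pos[r] for r in train_rows])
        return zscore_per_neuron(sub, fit_rows=fit), {r: i for i, r in enumerate(rows_used)}
    return zscore_per_neuron(sub), {r: i for i, r in enumerate(rows_used)}


def decode_traditional(
    session: SessionData,
    region,
    split: SplitSpec | None = None,
    spec: DecoderSpec | None = None,
    seed: int = 0,
    with_shuffle: bool = True,
    record_splits: bool = False,
) -> DecodingResult:
    """Same-image category decoding: per image, disjoint train/val/test
    trials; fresh neuron subsample and trial draw every repeat.

    ``record_splits`` stores each repeat's neuron columns and trial index
    splits in ``extra["splits"]`` (for audit/testing)."""
    split = split or SplitSpec()
    spec = spec or DecoderSpec()
    if split.n_train + split.n_val + split.n_test != split.trials_per_image:
        raise ValueError("n_train + n_val + n_test must equal trials_per_image")
    mat, meta, ids = build_population_matrix(session, region)
    regions = _column_regions(session, ids)
    groups = _image_groups(meta)
    deficient = [k for k, v in groups.items() if v.size < split.trials_per_image]
    if deficient:
        raise ValueError(
            f"images with fewer than {split.trials_per_image} trials: {sorted(deficient)}"
        )
    y_dog = (meta["category"] == DOG).to_numpy().astype(int)

    accs, scores, s_accs, s_scores = [], [], [], []
    splits = []
    for r in range(split.n_repeats):
        rng = np.random.default_rng([seed, r])
        cols = _subsample_columns(session, region, split.n_neurons, rng, regions)
        tr, va, te = [], [], []
        for k in sorted(groups):
            pick = rng.choice(groups[k], size=split.trials_per_image, replace=False)
            tr.extend(pick[: split.n_train])
            va.extend(pick[split.n_train : split.n_train + split.n_val])
            te.extend(pick[split.n_train + split.n_val :])
        tr, va, te = np.array(tr), np.array(va), np.array(te)
        if record_splits:
            splits.append(dict(columns=cols, train=tr, val=va, test=te))
        rows_used = np.concatenate([tr, va, te])
        Z, pos = _zscore_for_repeat(mat[:, cols], rows_used, tr, spec.zscore_scope)
        ztr = Z[[pos[i] for i in tr]]
        zva = Z[[pos[i] for i in va]]
        zte = Z[[pos[i] for i in te]]
        dec = train_decoder((ztr, y_dog[tr]), (zva, y_dog[va]), spec, seed=_mix(seed, r, 1))
        acc, sc = _accuracy_and_scores(dec, zte, y_dog[te])
        accs.append(acc)
        scores.append(sc)
        if with_shuffle:
            rng_s = np.random.default_rng([seed, r, 2])
            y_shuf = y_dog[tr][rng_s.permutation(tr.size)]
            dec_s = train_decoder((ztr, y_shuf), (zva, y_dog[va]), spec, seed=_mix(seed, r, 1))
            acc_s, sc_s = _accuracy_and_scores(dec_s, zte, y_dog[te])
            s_accs.append(acc_s)
            s_scores.append(sc_s)
    return DecodingResult(
        strategy="traditional",
        region=region,
        n_neurons=split.n_neurons,
        seed=seed,
        accuracies=np.array(accs),
        scores=scores,
        shuffled_accuracies=np.array(s_accs) if with_shuffle else None,
        shuffled_scores=s_scores if with_shuffle else None,
        extra={"splits": splits} if record_splits else {},
    )


def _mix(*parts: int) -> int:
    """Fold seed parts into one non-negative 31-bit integer (FNV-style)."""
    h = 1469598103934665603
    for p in parts:
        h = ((h ^ (p & 0xFFFFFFFF)) * 1099511628211) % (1 << 64)
    return h % (2**31)


def identity_folds(
    identities: Sequence[int], n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Seeded uniform-random partition of morph identities into folds."""
    ids = np.asarray(sorted(set(identities)))
    if n_folds > ids.size:
        raise ValueError(f"{n_folds} folds for {ids.size} identities")
    return [np.sort(f) for f in np.array_split(rng.permutation(ids), n_folds)]


def decode_generalization(
    session: SessionData,
    region,
    split: SplitSpec | None = None,
    spec: DecoderSpec | None = None,
    seed: int = 0,
    with_shuffle: bool = True,
    shuffle_validation: bool = True,
    record_splits: bool = False,
) -> DecodingResult:
    """Held-out-identity category decoding (k-fold over morph identities).

    Per repeat: fresh neuron subsample, fresh trial draws, and a full CV
    pass; test trials come only from images of the left-out identities, so
    above-chance accuracy requires category signal that transfers across
    morph identities. The shuffled control permutes training (and, by
    default, validation) labels; test labels are unchanged.
    """
    split = split or SplitSpec(n_train=5, n_val=1, n_test=0)
    spec = spec or DecoderSpec()
    if split.n_train + split.n_val != split.trials_per_image:
        raise ValueError("n_train + n_val must equal trials_per_image")
    mat, meta, ids = build_population_matrix(session, region)
    regions = _column_regions(session, ids)
    groups = _image_groups(meta)
    deficient = [k for k, v in groups.items() if v.size < split.trials_per_image]
    if deficient:
        raise ValueError(
            f"images with fewer than {split.trials_per_image} trials: {sorted(deficient)}"
        )
    y_dog = (meta["category"] == DOG).to_numpy().astype(int)
    idents = meta["morph_identity"].to_numpy()

    accs, scores, s_accs, s_scores = [], [], [], []
    splits = []
    for r in range(split.n_repeats):
        rng = np.random.default_rng([seed, r])
        cols = _subsample_columns(session, region, split.n_neurons, rng, regions)
        folds = identity_folds(idents, split.n_folds, rng)
        n_ok = n_tot = n_ok_s = 0
        rep_sc, rep_lab, rep_sc_s, rep_lab_s = [], [], [], []
        for fold in folds:
            test_ids = set(fold.tolist())
            tr, va, te = [], [], []
            for k in sorted(groups):
                pick = rng.choice(groups[k], size=split.trials_per_image, replace=False)
                if k[0] in test_ids:
                    te.extend(pick)
                else:
                    tr.extend(pick[: split.n_train])
                    va.extend(pick[split.n_train :])
            tr, va, te = np.array(tr), np.array(va), np.array(te)
            if record_splits:
                splits.append(dict(repeat=r, fold=fold, columns=cols,
                                   train=tr, val=va, test=te))
            rows_used = np.concatenate([tr, va, te])
            Z, pos = _zscore_for_repeat(mat[:, cols], rows_used, tr, spec.zscore_scope)
            ztr = Z[[pos[i] for i in tr]]
            zva = Z[[pos[i] for i in va]]
            zte = Z[[pos[i] for i in te]]
            dec = train_decoder((ztr, y_dog[tr]), (zva, y_dog[va]), spec,
                                seed=_mix(seed, r, 1, int(fold[0])))
            p = dec.predict_proba(zte)[:, 1]
            n_ok += int(np.sum((p >= 0.5).astype(int) == y_dog[te]))
            n_tot += te.size
            rep_sc.append(p)
            rep_lab.append(y_dog[te])
            if with_shuffle:
                rng_s = np.random.default_rng([seed, r, 2, int(fold[0])])
                ytr_s = y_dog[tr][rng_s.permutation(tr.size)]
                yva_s = (
                    y_dog[va][rng_s.permutation(va.size)]
                    if shuffle_validation
                    else y_dog[va]
                )
                dec_s = train_decoder((ztr, ytr_s), (zva, yva_s), spec,
                                      seed=_mix(seed, r, 1, int(fold[0])))
                ps = dec_s.predict_proba(zte)[:, 1]
                n_ok_s += int(np.sum((ps >= 0.5).astype(int) == y_dog[te]))
                rep_sc_s.append(ps)
                rep_lab_s.append(y_dog[te])
        accs.append(n_ok / n_tot)
        scores.append((np.concatenate(rep_sc), np.concatenate(rep_lab)))
        if with_shuffle:
            s_accs.append(n_ok_s / n_tot)
            s_scores.append((np.concatenate(rep_sc_s), np.concatenate(rep_lab_s)))
    return DecodingResult(
        strategy="generalization",
        region=region,
        n_neurons=split.n_neurons,
        seed=seed,
        accuracies=np.array(accs),
        scores=scores,
        shuffled_accuracies=np.array(s_accs) if with_shuffle else None,
        shuffled_scores=s_scores if with_shuffle else None,
        extra={"splits": splits} if record_splits else {},
    )


def shuffled_control(op, *args, **kwargs) -> DecodingResult:
    """Run a decoding operation and surface its paired shuffled control as
    the primary accuracies (draws identical to the unshuffled run)."""
    res = op(*args, with_shuffle=True, **kwargs)
    return replace(
        res,
        accuracies=res.shuffled_accuracies,
        scores=res.shuffled_scores,
        shuffled_accuracies=res.accuracies,
        shuffled_scores=res.scores,
        extra={**res.extra, "shuffled_control": True},
    )


def _fractional_split(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """80/10/10 index split; val/test round down but get at least 1 trial,
    remainder goes to train."""
    if n < 3:
        raise ValueError("need at least 3 trials per choice group")
    n_val = max(1, n // 10)
    n_test = max(1, n // 10)
    perm = rng.permutation(n)
    return perm[n_val + n_test :], perm[:n_val], perm[n_val : n_val + n_test]


def decode_choice(
    session: SessionData,
    region,
    split: SplitSpec | None = None,
    spec: DecoderSpec | None = None,
    seed: int = 0,
    with_shuffle: bool = True,
) -> DecodingResult:
    """Choice decoding on boundary-image trials, grouped by the animal's
    choice regardless of image, split 80/10/10 per choice group."""
    split = split or SplitSpec(n_repeats=500)
    spec = spec or DecoderSpec()
    mat, meta, ids = build_population_matrix(session, region, include_boundary=True)
    regions = _column_regions(session, ids)
    sel = (meta["category"] == BOUNDARY).to_numpy()
    mat = mat[sel]
    ch = meta["choice"].to_numpy()[sel]
    y = (ch == "second_interval").astype(int)
    g1, g0 = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    if g1.size == 0 or g0.size == 0:
        raise ValueError("both choices must be present among boundary trials")

    accs, scores, s_accs, s_scores = [], [], [], []
    for r in range(split.n_repeats):
        rng = np.random.default_rng([seed, r])
        cols = _subsample_columns(session, region, split.n_neurons, rng, regions)
        tr, va, te = [], [], []
        for g in (g0, g1):
            itr, iva, ite = _fractional_split(g.size, rng)
            tr.extend(g[itr]); va.extend(g[iva]); te.extend(g[ite])
        tr, va, te = np.array(tr), np.array(va), np.array(te)
        rows_used = np.concatenate([tr, va, te])
        Z, pos = _zscore_for_repeat(mat[:, cols], rows_used, tr, spec.zscore_scope)
        ztr = Z[[pos[i] for i in tr]]
        zva = Z[[pos[i] for i in va]]
        zte = Z[[pos[i] for i in te]]
        dec = train_decoder((ztr, y[tr]), (zva, y[va]), spec, seed=_mix(seed, r, 1))
        acc, sc = _accuracy_and_scores(dec, zte, y[te])
        accs.append(acc)
        scores.append(sc)
        if with_shuffle:
            rng_s = np.random.default_rng([seed, r, 2])
            dec_s = train_decoder((ztr, y[tr][rng_s.permutation(tr.size)]),
                                  (zva, y[va]), spec, seed=_mix(seed, r, 1))
            acc_s, sc_s = _accuracy_and_scores(dec_s, zte, y[te])
            s_accs.append(acc_s)
            s_scores.append(sc_s)
    return DecodingResult(
        strategy="choice",
        region=region,
        n_neurons=split.n_neurons,
        seed=seed,
        accuracies=np.array(accs),
        scores=scores,
        shuffled_accuracies=np.array(s_accs) if with_shuffle else None,
        shuffled_scores=s_scores if with_shuffle else None,
    )


# ---------------------------------------------------------------------------
# correct vs error


@dataclass
class CorrectErrorResult:
    """Per-day paired results (correct-trial test vs error-trial test) and
    the image/day exclusion ledger."""

    per_day: dict  # day -> (DecodingResult correct, DecodingResult error)
    ledger: dict


def correct_error_image_filter(
    sessions: Sequence[SessionData],
    min_correct: int,
    performance_threshold: float = 0.75,
) -> dict:
    """Apply the qualification rules and return the exclusion ledger.

    Days qualify when behavioral performance is at least the threshold.
    A low-ambiguity training image is excluded if on any qualifying day it
    has fewer than ``min_correct`` correct trials; its category partner
    (same identity, mirrored level: 0/100, 25/75) is then excluded too, and
    exclusions propagate across days. Ambiguous test images are excluded
    day-locally when they lack either a correct or an error trial that day.
    """
    qualifying = [s for s in sessions if behavioral_correct_rate(s) >= performance_threshold]
    skipped_days = [s.day for s in sessions if s not in qualifying]
    candidates = set()
    for s in qualifying:
        for t in s.trials:
            if t.image.morph_level in LOW_AMBIGUITY_LEVELS:
                candidates.add((t.image.morph_identity, t.image.morph_level))
    excluded: dict[tuple[int, int], str] = {}
    for s in qualifying:
        n_correct: dict[tuple[int, int], int] = {}
        for t in s.trials:
            k = (t.image.morph_identity, t.image.morph_level)
            if k in candidates and t.outcome == "correct":
                n_correct[k] = n_correct.get(k, 0) + 1
        for k in candidates:
            if n_correct.get(k, 0) < min_correct and k not in excluded:
                excluded[k] = f"fewer than {min_correct} correct trials on day {s.day}"
    for (ident, lev), why in list(excluded.items()):
        partner = (ident, _PARTNER_LEVEL[lev])
        if partner in candidates and partner not in excluded:
            excluded[partner] = f"partner of excluded image ({ident}, {lev})"
    train_images = sorted(candidates - set(excluded))
    test_images_per_day = {}
    for s in qualifying:
        have_c, have_e = set(), set()
        for t in s.trials:
            k = (t.image.morph_identity, t.image.morph_level)
            if t.image.morph_level in AMBIGUOUS_LEVELS:
                (have_c if t.outcome == "correct" else have_e).add(k)
        test_images_per_day[s.day] = sorted(have_c & have_e)
    return dict(
        qualifying_days=[s.day for s in qualifying],
        skipped_days=skipped_days,
        train_images=train_images,
        excluded_train_images={f"{k}": v for k, v in excluded.items()},
        test_images_per_day=test_images_per_day,
    )


def decode_correct_vs_error(
    sessions: Sequence[SessionData],
    region,
    split: SplitSpec | None = None,
    spec: DecoderSpec | None = None,
    min_correct: int = 3,
    performance_threshold: float = 0.75,
    seed: int = 0,
    with_shuffle: bool = True,
) -> CorrectErrorResult:
    """Category decoding trained on correct low-ambiguity trials and tested
    separately on ambiguous correct and ambiguous error trials, per day.

    Per repeat, ``min_correct`` correct trials per training image are drawn;
    one per image serves as validation, the rest train the decoder.
    """
    split = split or SplitSpec(n_repeats=200)
    spec = spec or DecoderSpec()
    ledger = correct_error_image_filter(sessions, min_correct, performance_threshold)
    train_images = set(tuple(k) for k in ledger["train_images"])
    if not train_images:
        raise ValueError(f"no qualifying training images; ledger: {ledger}")
    cats = {DOG if lv > 50 else "cat" for _, lv in train_images}
    if len(cats) < 2:
        raise ValueError(f"training images cover one category only; ledger: {ledger}")

    per_day = {}
    for s in sessions:
        if s.day not in ledger["qualifying_days"]:
            continue
        test_images = set(tuple(k) for k in ledger["test_images_per_day"][s.day])
        if not test_images:
            continue
        mat, meta, ids = build_population_matrix(s, region)
        regions = _column_regions(s, ids)
        key = list(zip(meta["morph_identity"], meta["morph_level"]))
        outcome = meta["outcome"].to_numpy()
        y_dog = (meta["category"] == DOG).to_numpy().astype(int)
        train_pool = {
            k: np.array([i for i, kk in enumerate(key) if kk == k and outcome[i] == "correct"])
            for k in sorted(train_images)
        }
        thin = [k for k, v in train_pool.items() if v.size < min_correct]
        if thin:
            raise ValueError(f"day {s.day}: training images with too few correct trials: {thin}")
        te_c = np.array([i for i, kk in enumerate(key) if kk in test_images and outcome[i] == "correct"])
        te_e = np.array([i for i, kk in enumerate(key) if kk in test_images and outcome[i] == "error"])

        acc_c, acc_e, sc_c, sc_e = [], [], [], []
        sacc_c, sacc_e = [], []
        for r in range(split.n_repeats):
            rng = np.random.default_rng([seed, s.day, r])
            cols = _subsample_columns(s, region, split.n_neurons, rng, regions)
            tr, va = [], []
            for k in sorted(train_pool):
                pick = rng.choice(train_pool[k], size=min_correct, replace=False)
                tr.extend(pick[:-1])
                va.append(pick[-1])
            tr, va = np.array(tr), np.array(va)
            rows_used = np.concatenate([tr, va, te_c, te_e])
            Z, pos = _zscore_for_repeat(mat[:, cols], rows_used, tr, spec.zscore_scope)
            ztr = Z[[pos[i] for i in tr]]
            zva = Z[[pos[i] for i in va]]
            zc = Z[[pos[i] for i in te_c]]
            ze = Z[[pos[i] for i in te_e]]
            dec = train_decoder((ztr, y_dog[tr]), (zva, y_dog[va]), spec,
                                seed=_mix(seed, s.day, r, 1))
            a, sc = _accuracy_and_scores(dec, zc, y_dog[te_c])
            acc_c.append(a); sc_c.append(sc)
            a, sc = _accuracy_and_scores(dec, ze, y_dog[te_e])
            acc_e.append(a); sc_e.append(sc)
            if with_shuffle:
                rng_s = np.random.default_rng([seed, s.day, r, 2])
                dec_s = train_decoder((ztr, y_dog[tr][rng_s.permutation(tr.size)]),
                                      (zva, y_dog[va]), spec, seed=_mix(seed, s.day, r, 1))
                sacc_c.append(float(np.mean(dec_s.predict(zc) == y_dog[te_c])))
                sacc_e.append(float(np.mean(dec_s.predict(ze) == y_dog[te_e])))
        mk = lambda tag, accs, scs, saccs: DecodingResult(
            strategy="correct_error",
            region=region,
            n_neurons=split.n_neurons,
            seed=seed,
            accuracies=np.array(accs),
            scores=scs,
            shuffled_accuracies=np.array(saccs) if with_shuffle else None,
            extra={"test_trials": tag, "day": s.day},
        )
        per_day[s.day] = (
            mk("correct", acc_c, sc_c, sacc_c),
            mk("error", acc_e, sc_e, sacc_e),
        )
    if not per_day:
        raise ValueError(f"no qualifying days with test images; ledger: {ledger}")
    return CorrectErrorResult(per_day=per_day, ledger=ledger)
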