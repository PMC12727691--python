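"""Per-neuron statistics: nested ANOVA with omega-squared effect size,
ROC category preference with a permutation null, selectivity labels, and
choice probability on boundary trials.

The nested ANOVA follows the factor structure category + morph identity +
morph level (nested within category), optionally with two-way interactions,
using a sequential (Type-I, in the listed order) sum-of-squares
decomposition computed by projection. Omega-squared,

    w2 = (SSQ_effect - df_effect * MS_error) / (SSQ_total + MS_error),

is the bias-corrected proportion of response variance attributable to a
factor; it ranges from -1 to 1 and is ~0 in expectation under the null.

ROC analysis treats dog-like images as the positive class: AUC > 0.5 means
higher firing for dogs. Significance comes from a permutation null (category
labels shuffled, default 1000 times) summarized by a Gaussian moment fit
(mean, SD); an AUC outside mu +- 1.96 sigma is significant. Cat-side
encoding strength is quantified as 1 - AUC so both categories are on a
common >=0.5 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BOUNDARY, CAT, DOG, SessionData, build_population_matrix

NESTED_FACTORS = ("category", "morph_identity", "morph_level(category)")


@dataclass
class AnovaResult:
    """Sequential ANOVA table plus error terms and per-factor omega-squared."""

    table: pd.DataFrame  # rows: factor, ss, df, F, p, omega_squared
    ms_error: float
    ss_total: float
    ss_error: float
    df_error: int

    def p(self, factor: str) -> float:
        return float(self.table.set_index("factor").loc[factor, "p"])

    def omega(self, factor: str) -> float:
        return float(self.table.set_index("factor").loc[factor, "omega_squared"])


def _indicator(labels: np.ndarray) -> np.ndarray:
    _, inv = np.unique(labels, return_inverse=True)
    out = np.zeros((labels.size, inv.max() + 1))
    out[np.arange(labels.size), inv] = 1.0
    return out


def _explained_ss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Model SS (around the fitted values' contribution) and rank of X."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fit = X @ coef
    resid = y - fit
    return float(y @ y - resid @ resid), int(rank)


def nested_anova(
    rates: Sequence[float],
    category: Sequence,
    morph_level: Sequence,
    morph_identity: Sequence,
    interactions: Sequence[str] = ("category:morph_identity",),
) -> AnovaResult:
    """Sequential nested ANOVA of per-trial rates.

    Factors enter in the order category, morph identity, morph level nested
    in category, then any requested two-way interactions
    (``"category:morph_identity"`` and/or ``"morph_identity:morph_level(category)"``).
    Boundary (50%) trials are excluded before fitting. Each (identity, level)
    cell must hold at least 2 trials.
    """
    y = np.asarray(rates, dtype=float)
    cat = np.asarray(category)
    lev = np.asarray(morph_level)
    ident = np.asarray(morph_identity)
    keep = cat != BOUNDARY
    y, cat, lev, ident = y[keep], cat[keep], lev[keep], ident[keep]
    n = y.size
    if n == 0:
        raise ValueError("no non-boundary trials")
    if len(np.unique(cat)) < 2:
        raise ValueError("both categories are required")

    cells = pd.Series(1, index=pd.MultiIndex.from_arrays([ident, lev]))
    counts = cells.groupby(level=[0, 1]).sum()
    thin = counts[counts < 2]
    if len(thin):
        cell = thin.index[0]
        raise ValueError(
            f"cell (identity={cell[0]}, level={cell[1]}) has fewer than 2 trials"
        )

    # nested level factor: level is only meaningful within its category
    lev_in_cat = np.array([f"{c}|{l}" for c, l in zip(cat, lev)])
    terms: list[tuple[str, np.ndarray]] = [
        ("category", _indicator(cat)),
        ("morph_identity", _indicator(ident)),
        ("morph_level(category)", _indicator(lev_in_cat)),
    ]
    known = {
        "category:morph_identity": np.array(
            [f"{c}*{i}" for c, i in zip(cat, ident)]
        ),
        "morph_identity:morph_level(category)": np.array(
            [f"{i}*{cl}" for i, cl in zip(ident, lev_in_cat)]
        ),
    }
    for name in interactions:
        if name not in known:
            raise ValueError(f"unknown interaction term {name!r}")
        terms.append((name, _indicator(known[name])))

    ybar = y - y.mean()
    ss_total = float(ybar @ ybar)
    X = np.ones((n, 1))
    prev_ss, prev_rank = 0.0, 1
    rows = []
    for name, block in terms:
        X = np.column_stack([X, block])
        ss_model, rank = _explained_ss(y - y.mean(), X)
        rows.append((name, ss_model - prev_ss, rank - prev_rank))
        prev_ss, prev_rank = ss_model, rank
    ss_error = ss_total - prev_ss
    df_error = n - prev_rank
    if df_error <= 0:
        raise ValueError("no residual degrees of freedom (too few replicates)")
    ms_error = ss_error / df_error

    table = []
    for name, ss, df in rows:
        df = max(df, 1)
        F = (ss / df) / ms_error if ms_error > 0 else np.inf
        p = float(stats.f.sf(F, df, df_error))
        w2 = omega_squared(ss, df, ms_error, ss_total)
        table.append(dict(factor=name, ss=ss, df=df, F=F, p=p, omega_squared=w2))
    return AnovaResult(
        table=pd.DataFrame(table),
        ms_error=ms_error,
        ss_total=ss_total,
        ss_error=ss_error,
        df_error=df_error,
    )


def omega_squared(
    ss_effect: float, df_effect: float, ms_error: float, ss_total: float
) -> float:
    """Bias-corrected effect size; ranges from -1 to 1."""
    denom = ss_total + ms_error
    if denom <= 0:
        raise ValueError("SSQ_total + MS_error must be positive")
    return (ss_effect - df_effect * ms_error) / denom


def omega_squared_oneway(rates: Sequence[float], category: Sequence) -> float:
    """Omega-squared of category from a one-way ANOVA (the pipeline default
    effect-size path; significance still comes from the nested model)."""
    y = np.asarray(rates, dtype=float)
    cat = np.asarray(category)
    keep = cat != BOUNDARY
    y, cat = y[keep], cat[keep]
    groups = [y[cat == c] for c in np.unique(cat)]
    if len(groups) < 2:
        raise ValueError("both categories are required")
    n = y.size
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_effect = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    df_effect = len(groups) - 1
    df_error = n - len(groups)
    ms_error = (ss_total - ss_effect) / df_error
    return omega_squared(ss_effect, df_effect, ms_error, ss_total)


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_auc(rates_dog: Sequence[float], rates_cat: Sequence[float]) -> float:
    """Threshold-sweep AUC with dog as the positive class.

    Equals the Mann-Whitney statistic U / (n_dog * n_cat) with ties counted
    one half.
    """
    d = np.asarray(rates_dog, dtype=float)
    c = np.asarray(rates_cat, dtype=float)
    if d.size == 0 or c.size == 0:
        raise ValueError("both rate lists must be non-empty")
    ranks = stats.rankdata(np.concatenate([d, c]))
    u = ranks[: d.size].sum() - d.size * (d.size + 1) / 2
    return float(u / (d.size * c.size))


@dataclass
class AucRecord:
    """ROC result for one neuron x morph identity with its permutation null."""

    neuron_id: str
    morph_identity: int
    auc: float
    null_mu: float
    null_sigma: float
    significant: bool
    preferred: str  # "dog", "cat", or "none"


def _rank_auc_null(
    ranks: np.ndarray, n_pos: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """AUCs of ``n_perm`` random relabelings, from precomputed ranks."""
    n = ranks.size
    n_neg = n - n_pos
    order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_pos]
    u = ranks[order].sum(axis=1) - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


def auc_significance(
    rates: Sequence[float],
    labels: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
    neuron_id: str = "",
    morph_identity: int = 0,
) -> AucRecord:
    """AUC of dog vs cat rates with a Gaussian-fit permutation null.

    The null is the sample mean and SD of ``n_perm`` label-shuffled AUCs
    (the moment fit is the maximum-likelihood Gaussian fit); the observed
    AUC is significant when it falls outside mu +- 1.96 sigma, with the
    exceeded side determining the preferred category.
    """
    y = np.asarray(rates, dtype=float)
    lab = np.asarray(labels)
    dog, cat = y[lab == DOG], y[lab == CAT]
    if dog.size == 0 or cat.size == 0:
        raise ValueError("both categories must be present")
    auc = roc_auc(dog, cat)
    ranks = stats.rankdata(np.concatenate([dog, cat]))
    rng = np.random.default_rng(seed)
    null = _rank_auc_null(ranks, dog.size, n_perm, rng)
    mu, sigma = float(null.mean()), float(null.std(ddof=0))
    if sigma == 0:
        warnings.warn("degenerate permutation null (sigma = 0); flagged not significant")
        return AucRecord(neuron_id, morph_identity, auc, mu, 0.0, False, "none")
    lo, hi = mu - 1.96 * sigma, mu + 1.96 * sigma
    significant = not (lo <= auc <= hi)
    preferred = "none"
    if significant:
        preferred = DOG if auc > hi else CAT
    return AucRecord(neuron_id, morph_identity, auc, mu, sigma, significant, preferred)


def cat_auc_transform(auc: float) -> float:
    """Fold an AUC to the cat side (1 - AUC) so cat-encoding strength is on
    the same >=0.5 scale as dog encoding."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must be in [0, 1]")
    return 1.0 - auc


@dataclass
class SelectivityLabel:
    neuron_id: str
    label: str  # "category_selective", "mixed_selectivity", or "none"


def classify_selectivity(records: Iterable[AucRecord]) -> SelectivityLabel:
    """Category-selective: significant AUCs all prefer one category across
    identities; mixed-selectivity: significant AUCs of both preferences."""
    records = list(records)
    if not records:
        raise ValueError("at least one AucRecord is required")
    neuron_id = records[0].neuron_id
    prefs = {r.preferred for r in records if r.significant}
    if not prefs:
        return SelectivityLabel(neuron_id, "none")
    if len(prefs) == 1:
        return SelectivityLabel(neuron_id, "category_selective")
    return SelectivityLabel(neuron_id, "mixed_selectivity")


@dataclass
class ChoiceProbabilityResult:
    folded_auc: float
    p_value: float
    significant: bool
    n_perm: int


def choice_probability(
    rates: Sequence[float],
    choices: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ChoiceProbabilityResult:
    """Folded choice AUC on (intended) boundary-image trials.

    Trials are grouped by the animal's choice, second-interval release being
    the positive class; AUCs below 0.5 are folded to 1 - AUC so the value
    measures discrimination strength regardless of direction. The permutation
    null shuffles choice labels and folds each permuted AUC the same way, so
    the test stays valid despite the folding.
    """
    y = np.asarray(rates, dtype=float)
    ch = np.asarray(choices)
    pos, neg = y[ch == "second_interval"], y[ch == "first_interval"]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both choices must be present")
    auc = roc_auc(pos, neg)
    folded = max(auc, 1.0 - auc)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    rng = np.random.default_rng(seed)
    null = _rank_auc_null(ranks, pos.size, n_perm, rng)
    null = np.maximum(null, 1.0 - null)
    p = (1.0 + np.sum(null >= folded)) / (n_perm + 1.0)
    return ChoiceProbabilityResult(folded, float(p), bool(p < alpha), n_perm)


# ---------------------------------------------------------------------------
# per-session tables


def session_anova_table(
    session: SessionData,
    region: str,
    interactions: Sequence[str] = ("category:morph_identity",),
) -> pd.DataFrame:
    """Nested-ANOVA category p and one-way omega-squared for every neuron."""
    mat, meta, ids = build_population_matrix(session, region)
    rates = mat / (session.window_ms / 1000.0)
    rows = []
    for j, nid in enumerate(ids):
        res = nested_anova(
            rates[:, j], meta["category"], meta["morph_level"],
            meta["morph_identity"], interactions=interactions,
        )
        rows.append(
            dict(
                neuron_id=nid,
                region=region,
                day=session.day,
                category_p=res.p("category"),
                identity_p=res.p("morph_identity"),
                level_p=res.p("morph_level(category)"),
                omega_squared=omega_squared_oneway(rates[:, j], meta["category"]),
            )
        )
    return pd.DataFrame(rows)


def category_significant_fraction(
    session: SessionData, region: str, alpha: float = 0.05, **kwargs
) -> float:
    """Fraction of the region's neurons with nested-ANOVA category p < alpha."""
    tab = session_anova_table(session, region, **kwargs)
    return float((tab["category_p"] < alpha).mean())


def session_auc_table(
    session: SessionData, region: str, n_perm: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Per neuron x morph identity AUC records for one region."""
    mat, meta, ids = build_population_matrix(session, region)
    rates = mat / (session.window_ms / 1000.0)
    rows = []
    for j, nid in enumerate(ids):
        for k, ident in enumerate(np.unique(meta["morph_identity"])):
            sel = meta["morph_identity"].to_numpy() == ident
            rec = auc_significance(
                rates[sel, j],
                meta["category"].to_numpy()[sel],
                n_perm=n_perm,
                seed=seed + 7919 * j + int(ident),
                neuron_id=nid,
                morph_identity=int(ident),
            )
            rows.append(
                dict(
                    neuron_id=rec.neuron_id, region=region, day=session.day,
                    morph_identity=rec.morph_identity, auc=rec.auc,
                    null_mu=rec.null_mu, null_sigma=rec.null_sigma,
                    significant=rec.significant, preferred=rec.preferred,
                )
            )
    return pd.DataFrame(rows)
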