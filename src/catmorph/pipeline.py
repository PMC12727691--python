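"""End-to-end orchestration: run the single-unit, decoding, and
representational stages over a multi-day experiment and evaluate the
cross-day learning statistics.

The headline qualitative signature of region-specific category learning is:
the fraction of category-modulated neurons, the population decoding
accuracy, and the between-category representational dissimilarity all rise
across days in TE but not TEO; region x day interactions are significant;
and decoding accuracy tracks behavioral performance in TE only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import SessionData, behavioral_correct_rate
from .decoding import SplitSpec, DecoderSpec, decode_traditional
from .learning_stats import (
    bh_fdr,
    bootstrap_corr_vs_day,
    fit_day_lm,
    fit_region_day_interaction,
)
from .representational import category_dissimilarity_summary
from .single_unit import session_anova_table


@dataclass
class ExperimentAnalysis:
    """Per-day stage outputs for one simulated or recorded experiment."""

    regions: tuple[str, ...]
    days: list[int]
    behavior: dict                      # day -> correct rate
    significant_fraction: dict          # region -> {day -> fraction}
    anova_tables: pd.DataFrame
    accuracies: dict                    # region -> {day -> repeat accuracies}
    shuffled_accuracies: dict           # region -> {day -> repeat accuracies}
    dissimilarity: pd.DataFrame         # day, region, pair_class, dissimilarity rows


def analyze_experiment(
    sessions: Sequence[SessionData],
    regions: tuple[str, ...] = ("TE", "TEO"),
    split: SplitSpec | None = None,
    spec: DecoderSpec | None = None,
    alpha: float = 0.05,
    seed: int = 0,
) -> ExperimentAnalysis:
    """Run the per-day stages (nested ANOVA per neuron, traditional decoding
    with shuffled control, cat-vs-dog dissimilarity) over an experiment."""
    split = split or SplitSpec(n_neurons=30, n_repeats=15)
    days = [s.day for s in sessions]
    behavior = {s.day: behavioral_correct_rate(s) for s in sessions}
    frac = {r: {} for r in regions}
    acc = {r: {} for r in regions}
    sacc = {r: {} for r in regions}
    anova_rows, dis_rows = [], []
    for s in sessions:
        for r in regions:
            tab = session_anova_table(s, r)
            anova_rows.append(tab)
            frac[r][s.day] = float((tab["category_p"] < alpha).mean())
            res = decode_traditional(s, r, split, spec, seed=seed)
            acc[r][s.day] = res.accuracies
            sacc[r][s.day] = res.shuffled_accuracies
            summ = category_dissimilarity_summary(s, r)
            pairs = summ.pairs.copy()
            pairs["day"] = s.day
            pairs["region"] = r
            dis_rows.append(pairs)
    return ExperimentAnalysis(
        regions=regions,
        days=days,
        behavior=behavior,
        significant_fraction=frac,
        anova_tables=pd.concat(anova_rows, ignore_index=True),
        accuracies=acc,
        shuffled_accuracies=sacc,
        dissimilarity=pd.concat(dis_rows, ignore_index=True),
    )


@dataclass
class LearningSignatures:
    """Cross-day statistics per region plus the divergence tests.

    ``*_positive`` flags mean "significantly increasing across days" at the
    stated alpha (slopes two-sided, required positive)."""

    fraction_slope: dict
    fraction_slope_p: dict
    fraction_positive: dict
    accuracy_boot_ci: dict
    accuracy_positive: dict
    dissimilarity_slope: dict
    dissimilarity_slope_p: dict
    dissimilarity_positive: dict
    behavior_boot_ci: dict
    behavior_positive: dict
    interaction_p: float
    interaction_positive: bool
    alpha: float


def learning_signatures(
    analysis: ExperimentAnalysis,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> LearningSignatures:
    """Evaluate the learning-curve statistics of an analyzed experiment.

    Per region: linear-model day slope of the significant-neuron fraction
    (day-level observations), bootstrap correlation-vs-day test of decoding
    accuracy against its shuffled control (repeat-level resampling),
    linear-model day slope of cat-vs-dog dissimilarity (pair-level
    observations, as in the per-pair n of the source analyses), and the
    bootstrap test of accuracy against behavioral performance. Divergence:
    region x day interaction on repeat-level accuracies.
    """
    days = sorted(analysis.days)
    out = dict(
        fraction_slope={}, fraction_slope_p={}, fraction_positive={},
        accuracy_boot_ci={}, accuracy_positive={},
        dissimilarity_slope={}, dissimilarity_slope_p={}, dissimilarity_positive={},
        behavior_boot_ci={}, behavior_positive={},
    )
    for r in analysis.regions:
        f = fit_day_lm([analysis.significant_fraction[r][d] for d in days], days)
        out["fraction_slope"][r] = f.slope
        out["fraction_slope_p"][r] = f.slope_p
        out["fraction_positive"][r] = bool(f.slope > 0 and f.slope_p < alpha)

        boot = bootstrap_corr_vs_day(
            analysis.accuracies[r], analysis.shuffled_accuracies[r],
            n_boot=n_boot, seed=seed,
        )
        out["accuracy_boot_ci"][r] = boot.ci
        out["accuracy_positive"][r] = bool(boot.significant and np.mean(boot.delta_r) > 0)

        dd = analysis.dissimilarity
        sel = (dd["region"] == r) & (dd["pair_class"] == "cat_vs_dog")
        f = fit_day_lm(dd.loc[sel, "dissimilarity"], dd.loc[sel, "day"])
        out["dissimilarity_slope"][r] = f.slope
        out["dissimilarity_slope_p"][r] = f.slope_p
        out["dissimilarity_positive"][r] = bool(f.slope > 0 and f.slope_p < alpha)

        boot = bootstrap_corr_vs_day(
            analysis.accuracies[r], analysis.shuffled_accuracies[r],
            n_boot=n_boot, seed=seed + 1, covariate=analysis.behavior,
        )
        out["behavior_boot_ci"][r] = boot.ci
        out["behavior_positive"][r] = bool(boot.significant and np.mean(boot.delta_r) > 0)

    metric, region, day = [], [], []
    for r in analysis.regions:
        for d in days:
            a = analysis.accuracies[r][d]
            metric.extend(a)
            region.extend([r] * len(a))
            day.extend([d] * len(a))
    inter = fit_region_day_interaction(metric, region, day)
    return LearningSignatures(
        **out,
        interaction_p=inter.pvalues["region:day"],
        interaction_positive=bool(
            inter.params["region:day"] > 0 and inter.pvalues["region:day"] < alpha
        ),
        alpha=alpha,
    )
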