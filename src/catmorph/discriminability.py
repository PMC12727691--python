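"""Discriminability (d') of decoder output scores for single and pooled
neural ensembles, with the four-way combination taxonomy.

For each decoding repeat, the separation of cat-trial and dog-trial decoder
scores is

    d' = |mu_cat - mu_dog| / sqrt(0.5 * (sigma2_cat + sigma2_dog)),

a non-saturating counterpart of decoding accuracy. Per-repeat d' vectors for
the TE, TEO, and pooled (equal neuron counts from both regions) ensembles
are compared by permutation tests:

* d'(TE+TEO) ~ max[d'(TE), d'(TEO)]  -> redundant / overlapping information
* d'(TE+TEO) > max                   -> complementary, partially independent
* d'(TE+TEO) ~ d'(TE) + d'(TEO)      -> fully independent information
* d'(TE+TEO) < max                   -> one region adds noise

Scores default to the pre-threshold sigmoid outputs on test trials; d' is
invariant to common positive affine rescalings of the scores, so the
logit-scale variant gives the same ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .decoding import DecodingResult
from .learning_stats import permutation_compare

VERDICTS = ("redundant", "complementary", "independent", "noise_adding")


def dprime(scores_cat: Sequence[float], scores_dog: Sequence[float]) -> float:
    """Discriminability index of two score distributions (always >= 0)."""
    a = np.asarray(scores_cat, dtype=float)
    b = np.asarray(scores_dog, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 scores per class")
    pooled = 0.5 * (a.var(ddof=1) + b.var(ddof=1))
    if pooled <= 0:
        raise ValueError("zero pooled variance")
    return float(abs(a.mean() - b.mean()) / np.sqrt(pooled))


def dprime_per_repeat(result: DecodingResult, scale: str = "sigmoid") -> np.ndarray:
    """d' of every decoding repeat's test-trial scores (label 1 = dog).

    ``scale="logit"`` maps the sigmoid outputs back to the linear decoder
    output before computing d'.
    """
    out = []
    for scores, labels in result.scores:
        s = np.asarray(scores, dtype=float)
        if scale == "logit":
            eps = np.finfo(float).tiny
            s = np.log(np.clip(s, eps, 1 - eps) / np.clip(1 - s, eps, 1 - eps))
        elif scale != "sigmoid":
            raise ValueError(f"unknown score scale {scale!r}")
        labels = np.asarray(labels)
        out.append(dprime(s[labels == 0], s[labels == 1]))
    return np.array(out)


@dataclass
class DPrimeResult:
    ensemble: str  # "TE", "TEO", or "combined"
    dprimes: np.ndarray
    n_neurons: int
    strategy: str


def ensemble_dprimes(
    result_te: DecodingResult,
    result_teo: DecodingResult,
    result_combined: DecodingResult,
    scale: str = "sigmoid",
) -> tuple[DPrimeResult, DPrimeResult, DPrimeResult]:
    """Per-repeat d' vectors for the two single-region ensembles and the
    pooled ensemble (which must use equal neuron counts from each region)."""
    ns = {len(r.scores) for r in (result_te, result_teo, result_combined)}
    if len(ns) != 1:
        raise ValueError("all three results must share the repeat structure")
    mk = lambda name, res: DPrimeResult(
        ensemble=name,
        dprimes=dprime_per_repeat(res, scale=scale),
        n_neurons=res.n_neurons,
        strategy=res.strategy,
    )
    return mk("TE", result_te), mk("TEO", result_teo), mk("combined", result_combined)


@dataclass
class CombinationVerdict:
    """How the pooled ensemble's d' relates to the single regions'."""

    verdict: str
    p_vs_max: float
    p_vs_sum: float
    mean_combined: float
    mean_max: float
    mean_sum: float
    alpha: float


def classify_combination(
    d_te: np.ndarray,
    d_teo: np.ndarray,
    d_combined: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> CombinationVerdict:
    """Assign one of the four combination verdicts from per-repeat d' vectors.

    The ``~`` relations are operationalized as two-sided permutation tests of
    the mean difference at level ``alpha``: combined vs the per-repeat max of
    the single regions, and combined vs their per-repeat sum.
    """
    d_te, d_teo, d_combined = map(np.asarray, (d_te, d_teo, d_combined))
    if not d_te.shape == d_teo.shape == d_combined.shape:
        raise ValueError("repeat counts must match across ensembles")
    d_max = np.maximum(d_te, d_teo)
    d_sum = d_te + d_teo
    p_max = permutation_compare(d_combined, d_max, n_perm=n_perm, seed=seed)
    p_sum = permutation_compare(d_combined, d_sum, n_perm=n_perm, seed=seed + 1)
    mc, mm, ms = d_combined.mean(), d_max.mean(), d_sum.mean()
    if p_max >= alpha:
        verdict = "redundant"
    elif mc < mm:
        verdict = "noise_adding"
    elif p_sum < alpha and mc < ms:
        verdict = "complementary"
    else:
        verdict = "independent"
    return CombinationVerdict(
        verdict=verdict,
        p_vs_max=p_max,
        p_vs_sum=p_sum,
        mean_combined=float(mc),
        mean_max=float(mm),
        mean_sum=float(ms),
        alpha=alpha,
    )
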