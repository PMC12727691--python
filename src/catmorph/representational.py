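"""Representational dissimilarity (1 - Pearson r) between population
response patterns, for image pairs drawn from *different* morph identities.

Each image's pattern is its trial-averaged response per neuron, z-scored per
neuron across the image set. Restricting pairs to different identities
avoids the within-sequence visual-similarity confound; boundary (50%) images
are excluded. Pairs are classed as cat-vs-dog (between categories),
cat-vs-cat, or dog-vs-dog (within category), and per-class means +- SEM over
pairs summarize a session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BOUNDARY, CAT, DOG, SessionData, StimulusImage, build_population_matrix

PAIR_CLASSES = ("cat_vs_dog", "cat_vs_cat", "dog_vs_dog")


def pattern_matrix(
    session: SessionData, region: str, include_boundary: bool = False,
    zscore_raw_trials: bool = False,
) -> tuple[np.ndarray, list[StimulusImage]]:
    """Images x neurons matrix of trial-averaged responses, z-scored per
    neuron across the image set.

    ``zscore_raw_trials`` applies the per-neuron z-score to single trials
    before averaging instead (the alternative reading of the normalization);
    the default normalizes the trial-averaged patterns, so dissimilarity
    depends only on pattern shape.
    """
    mat, meta, _ = build_population_matrix(session, region, include_boundary=include_boundary)
    if zscore_raw_trials:
        sd = mat.std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
        mat = (mat - mat.mean(axis=0)) / sd
    key = list(zip(meta["morph_identity"], meta["morph_level"]))
    images = sorted({StimulusImage(i, l) for i, l in key})
    rows = []
    for im in images:
        sel = [k == (im.morph_identity, im.morph_level) for k in key]
        rows.append(mat[np.asarray(sel)].mean(axis=0))
    M = np.array(rows)
    if not zscore_raw_trials:
        sd = M.std(axis=0, ddof=1)
        flat = sd == 0
        if np.any(flat):
            warnings.warn(f"{int(flat.sum())} neuron(s) with identical responses to all images")
            sd = np.where(flat, 1.0, sd)
        M = (M - M.mean(axis=0)) / sd
        M[:, flat] = 0.0
    return M, images


def mean_pattern(session: SessionData, region: str, image: StimulusImage) -> np.ndarray:
    """One image's trial-averaged, per-neuron z-scored population pattern."""
    M, images = pattern_matrix(session, region, include_boundary=True)
    try:
        row = images.index(image)
    except ValueError:
        raise ValueError(f"image {image} has no trials in this session") from None
    return M[row]


def pair_dissimilarity(pattern_a: np.ndarray, pattern_b: np.ndarray) -> float:
    """Correlation distance 1 - r between two population patterns (in [0, 2])."""
    a = np.asarray(pattern_a, dtype=float)
    b = np.asarray(pattern_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("patterns must have equal length >= 2")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance pattern")
    return float(1.0 - np.corrcoef(a, b)[0, 1])


def _pair_class(a: StimulusImage, b: StimulusImage) -> str | None:
    ca, cb = a.category, b.category
    if BOUNDARY in (ca, cb) or a.morph_identity == b.morph_identity:
        return None
    if ca == cb:
        return "cat_vs_cat" if ca == CAT else "dog_vs_dog"
    return "cat_vs_dog"


def enumerate_pairs(
    stimulus_set: Sequence[StimulusImage], pair_class: str
) -> list[tuple[StimulusImage, StimulusImage]]:
    """All unordered cross-identity image pairs of one class.

    For I identities with the standard 5 cat + 5 dog non-boundary levels the
    counts are 25*I*(I-1) between categories and C(5I, 2) - 10*I within each
    category.
    """
    if pair_class not in PAIR_CLASSES:
        raise ValueError(f"unknown pair class {pair_class!r}")
    if len({im.morph_identity for im in stimulus_set}) < 2:
        raise ValueError("stimulus set must span at least 2 identities")
    return [
        (a, b)
        for a, b in combinations(sorted(set(stimulus_set)), 2)
        if _pair_class(a, b) == pair_class
    ]


@dataclass
class DissimilarityTable:
    """Per-pair dissimilarities and per-class summary for one session/region."""

    pairs: pd.DataFrame    # image_a, image_b, pair_class, dissimilarity
    summary: pd.DataFrame  # pair_class, mean, sem, n_pairs


def category_dissimilarity_summary(
    session: SessionData, region: str, zscore_raw_trials: bool = False
) -> DissimilarityTable:
    """Dissimilarity of every cross-identity image pair, averaged by class.

    SEM is computed over pairs (the n printed with each class).
    Deterministic given the session: no randomness is involved.
    """
    M, images = pattern_matrix(session, region, zscore_raw_trials=zscore_raw_trials)
    C = np.corrcoef(M)
    rows = []
    for i, j in combinations(range(len(images)), 2):
        cls = _pair_class(images[i], images[j])
        if cls is None:
            continue
        rows.append(
            dict(
                image_a=f"{images[i].morph_identity}:{images[i].morph_level}",
                image_b=f"{images[j].morph_identity}:{images[j].morph_level}",
                pair_class=cls,
                dissimilarity=1.0 - C[i, j],
            )
        )
    pairs = pd.DataFrame(rows)
    summary = (
        pairs.groupby("pair_class")["dissimilarity"]
        .agg(mean="mean", sem=lambda x: stats.sem(x), n_pairs="count")
        .reset_index()
    )
    return DissimilarityTable(pairs=pairs, summary=summary)
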