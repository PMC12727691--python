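"""Data model and plain-text IO for trial-aligned two-region recordings.

A *session* is one day's worth of trials for one animal: each trial shows a
single image from a morph matrix (morph identity x morph level, where morph
level is the percent-dog content of the image), the animal reports the
category with a two-interval bar release, and spike counts in a fixed
response window are stored for every simultaneously recorded neuron in
areas TE and TEO.

Sessions are stored as three sibling plain-text files::

    <stem>.tsv          one row per trial; count columns named by neuron_id
    <stem>.neurons.tsv  neuron_id, region, day
    <stem>.meta.json    day, window_ms, and the full stimulus set

Counts, not rates, are stored; rate = count / window. Neurons are keyed per
(region, day) -- daily populations are independent samples, units are not
tracked across days.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Morph levels used in the morph matrix (percent dog content).
ALLOWED_LEVELS: tuple[int, ...] = (0, 25, 35, 40, 45, 50, 55, 60, 65, 75, 100)

CAT = "cat"
DOG = "dog"
BOUNDARY = "boundary"

REGIONS = ("TE", "TEO")

CHOICES = ("first_interval", "second_interval", "none")
OUTCOMES = ("correct", "error", "neither")


def assign_category(morph_level: int) -> str:
    """Map a morph level (percent dog) to its category label.

    Levels below 50% are ``cat``, above 50% are ``dog``, and the 50% image
    sits on the category boundary and belongs to neither category.
    """
    if morph_level not in ALLOWED_LEVELS:
        raise ValueError(
            f"unknown morph level {morph_level!r}; allowed levels are {ALLOWED_LEVELS}"
        )
    if morph_level < 50:
        return CAT
    if morph_level > 50:
        return DOG
    return BOUNDARY


@dataclass(frozen=True, order=True)
class StimulusImage:
    """One cell of the morph matrix: a morph identity at a morph level."""

    morph_identity: int
    morph_level: int

    def __post_init__(self):
        if self.morph_identity < 1:
            raise ValueError(f"morph_identity must be >= 1, got {self.morph_identity}")
        assign_category(self.morph_level)  # validates the level

    @property
    def category(self) -> str:
        return assign_category(self.morph_level)


@dataclass(frozen=True)
class NeuronMeta:
    """Identity of one recorded unit: id, region (TE or TEO), day."""

    neuron_id: str
    region: str
    day: int

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if self.day < 1:
            raise ValueError(f"day must be >= 1, got {self.day}")


@dataclass
class TrialRecord:
    """One trial: the image shown, the animal's choice and outcome, and one
    spike count per neuron recorded that day (aligned to the session roster)."""

    trial_id: int
    day: int
    image: StimulusImage
    choice: str
    outcome: str
    counts: np.ndarray

    def __post_init__(self):
        if self.choice not in CHOICES:
            raise ValueError(f"unknown choice {self.choice!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if np.any(self.counts < 0):
            raise ValueError(f"trial {self.trial_id}: negative spike count")


@dataclass
class SessionData:
    """One day's trials, neuron roster, and stimulus set."""

    day: int
    neurons: list[NeuronMeta]
    trials: list[TrialRecord]
    stimulus_set: list[StimulusImage]
    window_ms: float = 550.0

    def validate(self, repeat_range: tuple[int, int] | None = None) -> "SessionData":
        """Check all invariants; returns self so calls can be chained.

        ``repeat_range`` optionally enforces per-image repeat counts, e.g.
        (6, 14) for the monkey-T design or (9, 10) for monkey X.
        """
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")
        if len(set(self.stimulus_set)) != len(self.stimulus_set):
            raise ValueError("duplicate images in stimulus_set")
        ids = [n.neuron_id for n in self.neurons]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate neuron_id in roster")
        stimset = set(self.stimulus_set)
        n_neurons = len(self.neurons)
        repeats: dict[StimulusImage, int] = {}
        for row, t in enumerate(self.trials):
            if t.image not in stimset:
                raise ValueError(
                    f"row {row}: trial {t.trial_id} references image "
                    f"({t.image.morph_identity}, {t.image.morph_level}) "
                    "not in the stimulus set"
                )
            if len(t.counts) != n_neurons:
                raise ValueError(
                    f"row {row}: trial {t.trial_id} has {len(t.counts)} counts "
                    f"for a {n_neurons}-neuron roster"
                )
            if t.outcome == "neither" and t.image.category != BOUNDARY and t.choice != "none":
                raise ValueError(
                    f"row {row}: outcome 'neither' on a non-boundary, non-skipped trial"
                )
            if t.day != self.day:
                raise ValueError(f"row {row}: trial day {t.day} != session day {self.day}")
            repeats[t.image] = repeats.get(t.image, 0) + 1
        if repeat_range is not None:
            lo, hi = repeat_range
            bad = {im: k for im, k in repeats.items() if not lo <= k <= hi}
            if bad:
                raise ValueError(f"per-image repeat counts outside [{lo}, {hi}]: {bad}")
        return self

    @property
    def neuron_ids(self) -> list[str]:
        return [n.neuron_id for n in self.neurons]

    def region_indices(self, region: str) -> np.ndarray:
        return np.array([i for i, n in enumerate(self.neurons) if n.region == region], dtype=int)


@dataclass
class ExperimentConfig:
    """Stimulus-design and analysis sizing for one animal's experiment."""

    animal_label: str = "synthetic"
    n_identities: int = 10
    morph_levels: tuple[int, ...] = ALLOWED_LEVELS
    regions: tuple[str, ...] = REGIONS
    days: int = 5
    min_neurons_per_region: int = 8
    window_ms: float = 550.0
    seed: int = 0

    def __post_init__(self):
        if self.n_identities < 2:
            raise ValueError("n_identities must be >= 2")
        if self.days < 1:
            raise ValueError("days must be >= 1")
        for lv in self.morph_levels:
            assign_category(lv)


# ---------------------------------------------------------------------------
# tabular IO


def write_session(session: SessionData, path: str | Path) -> Path:
    """Write a session as the three-file plain-text dialect; returns the
    trial-table path. Field ordering is fixed, so output is byte-stable."""
    path = Path(path)
    session.validate()
    cols = {
        "trial_id": [t.trial_id for t in session.trials],
        "day": [t.day for t in session.trials],
        "morph_identity": [t.image.morph_identity for t in session.trials],
        "morph_level": [t.image.morph_level for t in session.trials],
        "choice": [t.choice for t in session.trials],
        "outcome": [t.outcome for t in session.trials],
    }
    counts = (
        np.array([t.counts for t in session.trials])
        if session.trials
        else np.zeros((0, len(session.neurons)), dtype=int)
    )
    for j, nid in enumerate(session.neuron_ids):
        cols[nid] = counts[:, j] if len(session.trials) else []
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    pd.DataFrame(
        {
            "neuron_id": session.neuron_ids,
            "region": [n.region for n in session.neurons],
            "day": [n.day for n in session.neurons],
        }
    ).to_csv(_neuron_path(path), sep="\t", index=False)
    meta = {
        "day": session.day,
        "window_ms": session.window_ms,
        "stimulus_set": [
            [im.morph_identity, im.morph_level] for im in session.stimulus_set
        ],
    }
    _meta_path(path).write_text(json.dumps(meta, indent=1) + "\n")
    return path


def _neuron_path(path: Path) -> Path:
    return path.with_suffix(".neurons.tsv")


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def load_session(path: str | Path) -> SessionData:
    """Load a session written by :func:`write_session`, validating invariants.

    Parse failures report the offending row of the trial table.
    """
    path = Path(path)
    trials_df = pd.read_csv(path, sep="\t")
    required = ["trial_id", "day", "morph_identity", "morph_level", "choice", "outcome"]
    missing = [c for c in required if c not in trials_df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    ndf = pd.read_csv(_neuron_path(path), sep="\t")
    for c in ("neuron_id", "region", "day"):
        if c not in ndf.columns:
            raise ValueError(f"{_neuron_path(path)}: missing required column {c!r}")
    neurons = [
        NeuronMeta(str(r.neuron_id), str(r.region), int(r.day)) for r in ndf.itertuples()
    ]
    meta = json.loads(_meta_path(path).read_text())
    stimulus_set = [StimulusImage(int(i), int(l)) for i, l in meta["stimulus_set"]]

    count_cols = [str(n.neuron_id) for n in neurons]
    missing = [c for c in count_cols if c not in trials_df.columns]
    if missing:
        raise ValueError(f"{path}: missing count column(s) for neuron(s) {missing}")
    trials = []
    for row, rec in enumerate(trials_df.itertuples(index=False)):
        rec = rec._asdict()
        counts = np.array([rec[c] for c in count_cols])
        if not np.all(counts == np.floor(counts)):
            raise ValueError(f"{path} row {row}: non-integer spike count")
        if np.any(counts < 0):
            raise ValueError(f"{path} row {row}: negative spike count")
        try:
            trials.append(
                TrialRecord(
                    trial_id=int(rec["trial_id"]),
                    day=int(rec["day"]),
                    image=StimulusImage(int(rec["morph_identity"]), int(rec["morph_level"])),
                    choice=str(rec["choice"]),
                    outcome=str(rec["outcome"]),
                    counts=counts.astype(int),
                )
            )
        except ValueError as e:
            raise ValueError(f"{path} row {row}: {e}") from e
    session = SessionData(
        day=int(meta["day"]),
        neurons=neurons,
        trials=trials,
        stimulus_set=stimulus_set,
        window_ms=float(meta["window_ms"]),
    )
    return session.validate()


# ---------------------------------------------------------------------------
# analysis-facing views


def build_population_matrix(
    session: SessionData, region: str | Sequence[str], include_boundary: bool = False
) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Trials x neurons count matrix for one region (or a region sequence,
    which pools their neurons), with row-aligned trial metadata.

    Boundary (50% morph) trials are dropped unless ``include_boundary``.
    Returns ``(matrix, trial_meta, neuron_ids)``.
    """
    regions = (region,) if isinstance(region, str) else tuple(region)
    for r in regions:
        if r not in REGIONS:
            raise ValueError(f"unknown region {r!r}")
    idx = np.concatenate(
        [session.region_indices(r) for r in regions]
    ) if regions else np.array([], dtype=int)
    if idx.size == 0:
        raise ValueError(f"no neurons recorded in region(s) {regions}")
    keep = [
        t for t in session.trials if include_boundary or t.image.category != BOUNDARY
    ]
    mat = np.array([t.counts[idx] for t in keep]).reshape(len(keep), len(idx))
    meta = pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in keep],
            "morph_identity": [t.image.morph_identity for t in keep],
            "morph_level": [t.image.morph_level for t in keep],
            "category": [t.image.category for t in keep],
            "choice": [t.choice for t in keep],
            "outcome": [t.outcome for t in keep],
        }
    )
    neuron_ids = [session.neurons[i].neuron_id for i in idx]
    return mat, meta, neuron_ids


def behavioral_correct_rate(session: SessionData) -> float:
    """Fraction of correct choices over scoreable non-boundary trials.

    Boundary (50%) images are excluded -- they have no correct answer -- as
    are skipped trials (outcome ``neither``).
    """
    n_correct = n_error = 0
    for t in session.trials:
        if t.image.category == BOUNDARY or t.outcome == "neither":
            continue
        if t.outcome == "correct":
            n_correct += 1
        else:
            n_error += 1
    total = n_correct + n_error
    if total == 0:
        raise ValueError("session has no scoreable (non-boundary, chosen) trials")
    return n_correct / total
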