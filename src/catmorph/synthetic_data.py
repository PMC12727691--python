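"""Generative model for two-region category-learning experiments.

The generator emulates the statistical structure the downstream analyses
assume: a morph-matrix stimulus design (identities x percent-dog levels), two
simultaneously recorded populations (TE, TEO) with region-specific category
gain that can grow across days, morph-level and identity tuning, spike-count
noise, and a logistic psychometric choice model.

Firing-rate model for neuron *n* of a region on day *d*, image
(identity *i*, level *L*), with ``s = (L - 50) / 50`` and category sign
``c = sign(L - 50)`` (cat = -1, dog = +1, boundary = 0)::

    rate = baseline
         + identity_tuning[n, i]                       # ~N(0, identity_tuning_sd)
         + level_gain * l[n, i] * s                    # signed level ramp
         + c * g_d * asym(c) * (rho_d * u[n] + (1 - rho_d) * v[n, i])
                               / sqrt(rho_d**2 + (1 - rho_d)**2)
         + u[n] * z_trial                              # shared trial noise
         (+ choice-coupling term on boundary trials)

rectified at zero before count sampling. ``u[n], v[n, i], l[n, i]`` are
random +-1 signs; ``u`` is the population axis *common to all identities*
while ``v`` and the level-ramp sign ``l`` are identity-specific, so the
shared-axis fraction ``rho`` alone controls how much category information
transfers to never-seen identities (generalization). The mixed axis is
normalized to unit energy so the total (within-identity) category signal is
independent of ``rho``.
``g_d = gain0 + slope * (d - 1)`` is the region's category gain on day *d*;
a zero slope is the null (no-learning) model. ``asym`` optionally scales the
dog-side signal to emulate dog-dominant plasticity.

Neuron parameters are redrawn independently every day: daily populations are
independent samples, mirroring untracked units across sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    BOUNDARY,
    ExperimentConfig,
    NeuronMeta,
    SessionData,
    StimulusImage,
    TrialRecord,
    assign_category,
    ALLOWED_LEVELS,
)


def generate_stimulus_set(
    n_identities: int, levels: Sequence[int] = ALLOWED_LEVELS
) -> list[StimulusImage]:
    """All ``n_identities x len(levels)`` images of the morph matrix."""
    for lv in levels:
        assign_category(lv)
    return [
        StimulusImage(i, lv) for i in range(1, n_identities + 1) for lv in levels
    ]


@dataclass
class GeneratorConfig:
    """Parameters of the generative model; see the module docstring.

    Rates are in Hz. ``category_gain`` maps region -> (initial gain,
    per-day slope). ``shared_axis_fraction`` (rho) may be a scalar, a
    per-day sequence, or a mapping region -> scalar/sequence (region-specific
    plasticity of the shared axis). ``noise`` is ``"poisson"`` or ``("gaussian", sigma)``.
    """

    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    n_neurons: Mapping[str, int] = field(default_factory=lambda: {"TE": 60, "TEO": 60})
    baseline_rate: float = 8.0
    category_gain: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"TE": (0.15, 0.15), "TEO": (0.35, 0.0)}
    )
    shared_axis_fraction: float | Sequence[float] | Mapping = 0.6
    level_gain: float = 1.0
    identity_tuning_sd: float = 2.0
    noise: str | tuple[str, float] = "poisson"
    repeats_per_image: tuple[int, int] = (6, 8)
    psychometric_slope: float | Sequence[float] = 2.0
    psychometric_bias: float | Sequence[float] = 0.0
    dog_gain_asymmetry: float = 1.0
    shared_noise_sd: Mapping[str, float] = field(default_factory=dict)
    shared_noise_across_regions: bool = False
    error_signal_attenuation: float = 1.0
    choice_coupling: float = 0.0
    seed: int = 0

    def rho(self, region: str, day: int) -> float:
        value = self.shared_axis_fraction
        if isinstance(value, Mapping):
            value = value[region]
        r = _per_day(value, day)
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"shared_axis_fraction must be in [0, 1], got {r}")
        return r

    def gain(self, region: str, day: int) -> float:
        g0, slope = self.category_gain[region]
        return g0 + slope * (day - 1)


def _per_day(value, day: int) -> float:
    if np.isscalar(value):
        return float(value)
    return float(value[day - 1])


@dataclass
class DayParams:
    """Per-day random neuron parameters of one region's population."""

    region: str
    u: np.ndarray            # (n,) shared category axis signs, +-1
    v: np.ndarray            # (n, n_identities) identity-specific signs, +-1
    identity_tuning: np.ndarray  # (n, n_identities) Hz offsets
    level_sign: np.ndarray   # (n, n_identities) +-1, identity-specific


def day_params(config: GeneratorConfig, day: int) -> dict[str, DayParams]:
    """Draw (reproducibly) the neuron parameters of every region for a day."""
    out = {}
    n_id = config.experiment.n_identities
    for k, region in enumerate(config.experiment.regions):
        rng = np.random.default_rng([config.seed % (2**31), day, k])
        n = int(config.n_neurons[region])
        if n < 1:
            raise ValueError(f"empty neuron roster for region {region}")
        out[region] = DayParams(
            region=region,
            u=rng.choice([-1.0, 1.0], size=n),
            v=rng.choice([-1.0, 1.0], size=(n, n_id)),
            identity_tuning=rng.normal(0.0, config.identity_tuning_sd, size=(n, n_id)),
            level_sign=rng.choice([-1.0, 1.0], size=(n, n_id)),
        )
    return out


def mean_rate(
    config: GeneratorConfig,
    region: str,
    neuron_index: int,
    image: StimulusImage,
    day: int,
    params: Mapping[str, DayParams] | None = None,
) -> float:
    """Noise-free mean firing rate (Hz, rectified at 0) for one neuron."""
    params = params if params is not None else day_params(config, day)
    p = params[region]
    i = image.morph_identity - 1
    s = (image.morph_level - 50) / 50.0
    c = float(np.sign(image.morph_level - 50))
    rho = config.rho(region, day)
    asym = config.dog_gain_asymmetry if c > 0 else 1.0
    rate = (
        config.baseline_rate
        + p.identity_tuning[neuron_index, i]
        + config.level_gain * p.level_sign[neuron_index, i] * s
        + c * config.gain(region, day) * asym
        * (rho * p.u[neuron_index] + (1 - rho) * p.v[neuron_index, i])
        / np.sqrt(rho**2 + (1 - rho) ** 2)
    )
    return max(0.0, rate)


def _psychometric_p_second(config: GeneratorConfig, level: int, day: int) -> float:
    """P(release in the second interval | morph level), logistic in the
    signed distance from the category boundary."""
    slope = _per_day(config.psychometric_slope, day)
    bias = _per_day(config.psychometric_bias, day)
    from scipy.special import expit

    return float(expit(slope * (level - 50) / 50.0 + bias))


def simulate_session(config: GeneratorConfig, day: int) -> SessionData:
    """Simulate one day: stimulus presentation, choices, outcomes, counts.

    Fully reproducible from ``config.seed`` and ``day``.
    """
    exp = config.experiment
    if not 1 <= day <= exp.days:
        raise ValueError(f"day {day} outside [1, {exp.days}]")
    params = day_params(config, day)
    rng = np.random.default_rng([config.seed % (2**31), day, 997])

    stimulus_set = generate_stimulus_set(exp.n_identities, exp.morph_levels)
    lo, hi = config.repeats_per_image
    images: list[StimulusImage] = []
    for im in stimulus_set:
        images.extend([im] * int(rng.integers(lo, hi + 1)))
    order = rng.permutation(len(images))
    images = [images[j] for j in order]
    n_trials = len(images)

    # behavioral choices and outcomes
    levels = np.array([im.morph_level for im in images])
    cats = np.array([im.category for im in images])
    p_second = np.array([_psychometric_p_second(config, lv, day) for lv in levels])
    second = rng.random(n_trials) < p_second
    choices = np.where(second, "second_interval", "first_interval")
    outcomes = np.where(
        cats == BOUNDARY,
        "neither",
        np.where(
            (second & (cats == "dog")) | (~second & (cats == "cat")), "correct", "error"
        ),
    )

    regions = list(exp.regions)
    neurons = [
        NeuronMeta(f"{r}_{day:02d}_{j:03d}", r, day)
        for r in regions
        for j in range(int(config.n_neurons[r]))
    ]

    # mean-rate matrix, trials x neurons, assembled region by region
    window_s = exp.window_ms / 1000.0
    ids = np.array([im.morph_identity - 1 for im in images])
    s = (levels - 50) / 50.0
    c = np.sign(levels - 50).astype(float)
    asym = np.where(c > 0, config.dog_gain_asymmetry, 1.0)
    atten = np.where(outcomes == "error", config.error_signal_attenuation, 1.0)
    choice_sign = np.where(cats == BOUNDARY, np.where(second, 1.0, -1.0), 0.0)

    z_common = rng.normal(size=n_trials)
    blocks = []
    for r in regions:
        p = params[r]
        g = config.gain(r, day)
        rho = config.rho(r, day)
        cat_amp = (c * g * asym * atten)[:, None] * (
            rho * p.u[None, :] + (1 - rho) * p.v[:, ids].T
        ) / np.sqrt(rho**2 + (1 - rho) ** 2)
        z_sd = float(config.shared_noise_sd.get(r, 0.0))
        z = z_common if config.shared_noise_across_regions else rng.normal(size=n_trials)
        rate = (
            config.baseline_rate
            + p.identity_tuning[:, ids].T
            + config.level_gain * (p.level_sign[:, ids].T * s[:, None])
            + cat_amp
            + z_sd * z[:, None] * p.u[None, :]
            + config.choice_coupling * choice_sign[:, None] * p.u[None, :]
        )
        blocks.append(np.maximum(rate, 0.0))
    rates = np.concatenate(blocks, axis=1)

    if config.noise == "poisson":
        counts = rng.poisson(rates * window_s)
    else:
        kind, sigma = config.noise
        if kind != "gaussian":
            raise ValueError(f"unknown noise model {config.noise!r}")
        counts = np.maximum(
            np.rint(rates * window_s + rng.normal(0.0, sigma, size=rates.shape)), 0
        ).astype(int)

    trials = [
        TrialRecord(
            trial_id=k + 1,
            day=day,
            image=images[k],
            choice=str(choices[k]),
            outcome=str(outcomes[k]),
            counts=counts[k],
        )
        for k in range(n_trials)
    ]
    return SessionData(
        day=day,
        neurons=neurons,
        trials=trials,
        stimulus_set=stimulus_set,
        window_ms=exp.window_ms,
    ).validate(repeat_range=(lo, hi))


def simulate_learning_experiment(config: GeneratorConfig) -> list[SessionData]:
    """One session per day, with an independent neuron roster each day."""
    return [simulate_session(config, d) for d in range(1, config.experiment.days + 1)]


# ---------------------------------------------------------------------------
# named fixtures


def paper_like_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Learning profile with TE-only plasticity.

    TE category gain grows across days while TEO's stays flat (but starts
    higher, so the early-day representation is TEO-dominant); the shared-axis
    fraction grows with training, so generalization improves alongside
    specificity; the psychometric slope rises day by day.
    """
    exp = ExperimentConfig(animal_label="paper_like", n_identities=10, days=5, seed=seed)
    cfg = GeneratorConfig(
        experiment=exp,
        n_neurons={"TE": 60, "TEO": 60},
        category_gain={"TE": (0.15, 0.15), "TEO": (0.35, 0.0)},
        shared_axis_fraction={"TE": (0.4, 0.5, 0.6, 0.7, 0.8), "TEO": 0.4},
        psychometric_slope=(1.5, 2.5, 3.5, 4.5, 5.5),
        seed=seed,
    )
    return replace(cfg, **overrides)


def null_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Category-null model: no category-correlated signal at all.

    Both the category gain and the morph-level ramp are zeroed -- a monotone
    level ramp straddles the boundary and therefore carries category
    information by construction, so a calibrated null must drop it.
    Identity tuning (orthogonal to category) is kept.
    """
    cfg = paper_like_config(seed)
    cfg = replace(
        cfg,
        category_gain={"TE": (0.0, 0.0), "TEO": (0.0, 0.0)},
        level_gain=0.0,
        shared_axis_fraction=0.6,
        psychometric_slope=2.0,
    )
    return replace(cfg, **overrides)


def monkey_t_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Monkey-T-style design sizes: 10 identities, 9 days, 6-14 repeats,
    550 ms window, 8-neuron decoding subsample."""
    exp = ExperimentConfig(
        animal_label="T", n_identities=10, days=9, min_neurons_per_region=8,
        window_ms=550.0, seed=seed,
    )
    cfg = paper_like_config(seed)
    cfg = replace(
        cfg,
        experiment=exp,
        repeats_per_image=(6, 14),
        shared_axis_fraction={"TE": tuple(np.linspace(0.4, 0.8, 9)), "TEO": 0.4},
        psychometric_slope=tuple(np.linspace(1.5, 5.5, 9)),
        category_gain={"TE": (0.15, 0.075), "TEO": (0.35, 0.0)},
    )
    return replace(cfg, **overrides)


def monkey_x_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Monkey-X-style design sizes: 20 identities, 5 days, 9-10 repeats,
    530 ms window, 59-neuron decoding subsample."""
    exp = ExperimentConfig(
        animal_label="X", n_identities=20, days=5, min_neurons_per_region=59,
        window_ms=530.0, seed=seed,
    )
    cfg = paper_like_config(seed)
    cfg = replace(cfg, experiment=exp, repeats_per_image=(9, 10),
                  n_neurons={"TE": 80, "TEO": 80})
    return replace(cfg, **overrides)


def ensemble_regime_config(kind: str, seed: int = 0) -> GeneratorConfig:
    """Single-day fixtures for the pooled-ensemble d' taxonomy.

    All three regimes put the category signal on the shared axis (rho = 1)
    and add trial-to-trial noise along that axis, so single-region d' is
    noise-limited rather than neuron-count-limited:

    ``redundant``
        both regions read out the same signal *and* share one noise channel
        (``shared_noise_across_regions``), so pooling adds essentially
        nothing: d'(TE+TEO) ~ max.
    ``complementary``
        equal signal but independent per-region noise channels; pooling
        averages the noise down: max < d'(TE+TEO) < sum.
    ``noise``
        only TE carries signal; TEO contributes signal-free correlated
        variability that a decoder fit on few trials partly absorbs:
        d'(TE+TEO) < max.

    Use :data:`ENSEMBLE_REGIME_SPLITS` for the matching decoding geometry
    (the noise regime needs small training sets and many repeats).
    """
    if kind not in ("redundant", "complementary", "noise"):
        raise ValueError(f"unknown ensemble regime {kind!r}")
    n_id = {"redundant": 8, "complementary": 4, "noise": 2}[kind]
    n_nr = {"redundant": 32, "complementary": 16, "noise": 24}[kind]
    gain = {"TE": (2.0, 0.0), "TEO": (0.0, 0.0) if kind == "noise" else (2.0, 0.0)}
    sz_te = {"redundant": 6.0, "complementary": 2.5, "noise": 4.0}[kind]
    sz_teo = {"redundant": 6.0, "complementary": 2.5, "noise": 2.0}[kind]
    # the redundant regime minimizes nuisance tuning: with a dominant common
    # noise channel and homogeneous gains, d' is invariant to the readout
    # weighting, which is exactly what makes pooling uninformative
    it_sd = 0.5 if kind == "redundant" else 1.0
    lg = 0.0 if kind == "redundant" else 0.5
    exp = ExperimentConfig(animal_label=f"ensemble_{kind}", n_identities=n_id, days=1, seed=seed)
    return GeneratorConfig(
        experiment=exp,
        n_neurons={"TE": n_nr, "TEO": n_nr},
        category_gain=gain,
        shared_axis_fraction=1.0,
        identity_tuning_sd=it_sd,
        level_gain=lg,
        repeats_per_image=(6, 6),
        shared_noise_sd={"TE": sz_te, "TEO": sz_teo},
        shared_noise_across_regions=(kind == "redundant"),
        seed=seed,
    )


#: Decoding geometry matched to each d' regime: (trials_per_image, n_train,
#: n_val, n_test, n_neurons subsampled per region, n_repeats).
ENSEMBLE_REGIME_SPLITS = {
    "redundant": (6, 4, 1, 1, 8, 16),
    "complementary": (6, 4, 1, 1, 12, 30),
    "noise": (6, 2, 2, 2, 24, 400),
}
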