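# Methods

## The scientific setting

Two inferior-temporal subregions, TE and TEO, are recorded simultaneously
with chronic arrays while a subject learns to categorize morphed cat/dog
images in a two-interval forced choice. The stimulus set is a morph matrix:
morph identities (unique prototype pairs) crossed with morph levels (percent
dog: 0–100 in eleven steps concentrated near the boundary). Units are not
tracked across sessions, so each day's population is an independent sample;
all cross-day statements are about population statistics, not about
individual neurons changing.

Two distinct abilities are probed. *Specificity* — separating exemplars of
the two categories — is measured by same-image decoding and by single-unit
category statistics. *Generalization* — categorizing images from morph
sequences never seen during decoder training — is measured by
held-out-identity decoding and by cross-identity representational
dissimilarity. The pipeline's headline contrast is region-specific learning:
category information that grows across days in TE but not TEO, tracks
behavior in TE only, and diverges between regions (region × day
interaction).

## Generative model

Spike counts are Poisson (optionally Gaussian) around a rectified linear
rate. For neuron *n* on day *d*, image (identity *i*, level *L*), with
`s = (L − 50)/50` and category sign `c = sign(L − 50)`:

```
rate = baseline + t[n, i] + level_gain · l[n, i] · s
     + c · g_d(region) · asym(c) · (ρ·u[n] + (1−ρ)·v[n, i]) / √(ρ² + (1−ρ)²)
     + shared_noise_sd · u[n] · z_trial  (+ choice coupling on boundary trials)
```

* `u` is a ±1 population axis common to all identities; `v` and the
  level-ramp sign `l` are ±1 per identity. The shared-axis fraction ρ
  therefore controls exactly how much category information transfers to
  held-out identities; the mixed axis is normalized to unit energy so that ρ
  reallocates signal between shared and identity-specific components without
  changing the within-identity signal. ρ may be given per region: in the
  TE-plasticity profile only TE's ρ grows with training, because a globally
  growing ρ measurably raises TEO decoding too (a shared axis is easier to
  estimate from finite trials), contradicting the profile's TEO-flat premise.
* `g_d = gain0 + slope·(d−1)` is the region's category gain; slope 0 is the
  no-learning null. `asym` optionally scales the dog-side signal to emulate
  dog-dominant plasticity.
* `z_trial` is trial-to-trial noise along the category axis, per region or
  common to both regions. It exists so that pooled-ensemble discriminability
  can saturate (redundancy): with purely private noise, pooling neurons
  always helps and redundancy is unobservable.
* Choices follow a logistic psychometric
  `P(second interval) = σ(slope_d · s + bias_d)`; outcomes are scored against
  the true category, boundary trials have no correct answer. Optional hooks:
  error-trial attenuation of the category term (drives correct-vs-error
  contrasts) and a choice-coupling term on boundary trials (drives
  choice-probability and choice-decoding effects). All three hooks default to
  off.

**Default study conditions** (`paper_like_config`): 10 identities × 11
levels, 5 days, 60 neurons per region, 6–8 repeats per image, 550 ms count
window, baseline 8 Hz, identity tuning SD 2 Hz, level gain 1 Hz, TE gain
0.15 Hz + 0.15 Hz/day, TEO gain 0.35 Hz flat (TEO starts stronger, matching
the early-learning crossover), TE ρ 0.4→0.8, TEO ρ 0.4, psychometric slope
1.5→5.5 (behavior ≈64%→81% correct). Gains were sized from per-neuron
signal-to-noise arithmetic (per-neuron d′ = 2g/σ with σ ≈ √(rate·window)/window
≈ 3.8 Hz) so that per-neuron category d′ stays well below 1 — as in cortical
data, category information is a population-pooling phenomenon — and
population accuracy spans the realistic 0.55–0.85 range rather than
saturating.

**What the generator does not emulate:** temporal dynamics within the count
window, adaptation, noise correlations beyond the single shared axis,
reaction times, eye movements, and reward-size bookkeeping. Passing tests
therefore validate the statistical machinery and its calibration under this
model, not the neural claims themselves on recorded data.

## Single-unit statistics

The nested ANOVA uses a sequential (Type-I) projection decomposition in the
order category → morph identity → level-within-category → optional two-way
interactions (category × identity by default; identity × level-in-category
selectable). Boundary (50%) trials are excluded; each (identity, level) cell
must have ≥ 2 trials. Sums of squares are computed as explained-SS
increments of least-squares projections, which handles the rank-deficient
nested indicators exactly; on balanced designs this reproduces the group-mean
arithmetic oracle used in the tests. Omega-squared is exposed both as raw
arithmetic on any factor's ANOVA terms and as the pipeline-default one-way
(category) convenience; significance always comes from the nested model.

ROC analysis treats dog as the positive class; AUC is the Mann–Whitney
statistic with ties counted ½ (the threshold-sweep integral). The permutation
null (1000 label shuffles, vectorized over rank sums) is summarized by its
moments — the moment fit *is* the maximum-likelihood Gaussian fit, with no
binning ambiguity — and the ±1.96σ rule decides significance and preferred
category. Cat-side strength is reported as 1 − AUC. Choice probability folds
the AUC to max(AUC, 1 − AUC) and folds every permuted AUC the same way, so
the test remains level despite folding. A degenerate null (σ = 0, e.g. a
silent neuron) is flagged not-significant with a warning.

## Decoding

The decoder is one linear unit with sigmoid output trained on cross-entropy
by full-batch gradient descent with a bold-driver step size (grow 5% on
accepted epochs, undo and halve on rejections) — a deterministic gradient
method satisfying the stopping contract: patience of 6 consecutive
validation-error increases (minimum-validation weights returned), gradient
norm < 1e-7, or 10,000 epochs. The decision threshold on the sigmoid output
is 0.5. Z-scoring is fit per neuron on the repeat's full trial draw by
default, matching the unconditional normalization described for this design;
a leakage-free variant (fit on training rows only,
`DecoderSpec(zscore_scope="train")`) is available and recommended for new
studies.

Split geometries: traditional 4/1/1 of 6 trials per image (7/1/1 of 9 in the
larger-design preset); generalization 10 identity folds with 5/1 train/val
per in-fold image and all drawn trials of held-out-identity images as test;
choice 80/10/10 per choice group (val/test round down, at least 1 each,
remainder to train); correct-vs-error trains on correct trials of
low-ambiguity images (levels 0/25/75/100; per repeat, min-correct draws per
image with one held out for validation) and tests on ambiguous-image
(35–65%) correct and error trials separately. Qualification rules for
correct-vs-error: days at ≥75% behavioral performance; a training image is
excluded if any qualifying day gives it fewer than the minimum correct
trials, its mirrored-level partner is excluded with it, and exclusions
propagate across days; test images are excluded day-locally when they lack
either outcome. An exclusion ledger is attached to the result.

Shuffled controls permute training labels only, reusing the paired run's
neuron subsample and trial draws; the generalization variant also permutes
validation labels (its validation trials come from the training pool), and a
flag restores the unshuffled-validation behavior. Trial sampling is without
replacement and insufficient trials are an error, mirroring fixed-count
selection. Identity-fold assignment is a seeded uniform permutation.

Pooled ("combined") ensembles subsample the same number of neurons from each
region as the single-region runs use.

## d′ and the combination taxonomy

Per decoding repeat, d′ is computed from the pre-threshold sigmoid outputs
of test trials (a logit-scale variant is available; d′ is invariant to
positive affine maps, so the choice does not affect ordering). The taxonomy
operationalizes the ≈/</> relations as two-sided permutation tests on
repeat-level d′ vectors at α = 0.05: not distinguishable from the per-repeat
max of the single regions → redundant (significantly below it →
noise-adding); significantly above the max and below the per-repeat sum →
complementary; not below the sum → independent. The mean-difference
statistic makes the repeat-level and repeat-mean readings coincide.

The three named regimes put all signal on the shared axis with
axis-aligned trial noise: *redundant* shares one noise channel across
regions with homogeneous gains (then d′ is nearly invariant to readout
weighting, so pooling adds nothing; nuisance tuning is minimized because
realized pool asymmetries otherwise create small genuine deficits);
*complementary* gives each region an independent channel (pooling averages
noise down); *noise* gives TEO correlated variability and no signal, with
deliberately small training sets (60 trials vs 48 pooled features) so the
decoder's residual weight on the uninformative region measurably costs
discriminability — the regime needs many repeats (400) because the cost per
session is real but small.

## Learning statistics

Day slopes come from OLS with day coded 1, 2, 3, …; divergence from the full
region × day interaction model with region coded 0 = TEO, 1 = TE. Repeat-level
metrics (decoding accuracies) are tested against their shuffled controls by
bootstrap (5000 draws by default): repeats are resampled with replacement
within each day, day means correlated against day number (or a per-day
covariate such as behavioral performance), and the real-minus-shuffled
correlation difference is significant when its percentile CI excludes 0;
day labels are never resampled. One-value-per-day metrics use the paired
observation bootstrap of the correlation difference; CI sidedness is a
per-call parameter. Permutation p-values use the add-one convention
(b+1)/(n+1). BH-FDR adjustment is the standard step-up (via statsmodels),
applied across days when day-wise comparisons form a family. Partial
correlations residualize both variables on the covariates and use the
t-transform with df = n − k − 2. Behavior–accuracy regressions always include
the subject as a fixed 0/1 covariate and compare the {TE}, {TEO}, {TE+TEO}
predictor sets by AIC/BIC. Psychometric fits are 2-parameter logistic ML
with the slope capped (default 50) for separable data.

## Numerical and design choices

* Counts, not rates, are stored; rate = count/window. Rates are rectified at
  zero *before* sampling so the mean stays interpretable.
* The sequential decomposition makes factor order part of the model
  definition; the order above follows the factor listing of the analysis the
  pipeline implements. Near-balanced designs (repeat counts varying by ±2)
  make order effects negligible; tests pin exactness on balanced fixtures.
* Seeds: every stochastic operation takes a seed; per-repeat streams are
  derived with `numpy.random.default_rng([seed, repeat, ...])` and an
  FNV-style fold for decoder initializations, so runs are bit-reproducible
  and sub-streams independent.
* The learning-signature evaluation fits the significant-neuron fraction at
  day level (5 observations), decoding accuracy at repeat level (as in the
  analyses it mirrors), and dissimilarity at pair level (the per-pair n
  quoted with such analyses). Pair- and repeat-level fits treat clustered
  observations as independent and are anticonservative for flat series —
  under the TEO-flat profile the pair-level dissimilarity slope false-fires
  at roughly 10% rather than 5%, which the recovery tests accommodate by
  checking each signature component at a 90% reproduction rate.
* Degenerate inputs: constant neuron columns z-score to zeros with a
  warning; zero-variance patterns are an error in pair dissimilarity; a
  degenerate permutation null is not-significant with a warning; empty
  regions, single-class training sets, single-choice sessions, and
  insufficient trials are errors.

## Known limitations

* Calibration claims are exact only under exchangeability; Poisson counts
  make the ANOVA F-test approximate (measured ≈5–6% at nominal 5% under the
  category null at these sizes).
* Within one session, decoding repeats share the finite trial pool, so
  repeat means do not converge to ensemble truth; chance-level properties
  (e.g. generalization at ρ = 0) are cross-session statements and are tested
  as such.
* The bold-driver optimizer satisfies, but is not identical to, the scaled
  conjugate gradient training the decoder contract abstracts over; results
  are contract-level, not optimizer-level.
* The correct-vs-error stage implements the traditional-decoder variant;
  a generalization-strategy rerun of that analysis is not included.
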