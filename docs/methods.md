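# Methods

`taplearn` implements a stratification-and-response pipeline for a
sequential finger-tapping training study: participants practice a
nine-digit sequence on four buttons over 5 or 10 daily sessions of six
90-second training blocks (plus one daily catch block with a different
sequence and, before training on day 1, a single baseline block), while
receiving verum or placebo anodal tDCS over M1. The pipeline labels each
participant an *optimal* or *suboptimal* learner from the shape of their
accuracy learning curve, trains a classifier that predicts that label from
baseline ability alone, converts classifier margins into a likelihood of
benefiting from stimulation, splits each class into high/low tiers, and
tests for differential stimulation effects on accuracy dynamics per tier.
A synthetic cohort generator with known ground truth exercises every
stage.

## Performance metrics

A block's **accuracy** is correct presses / total presses and its
**speed** is correct presses per second. Press-level ratios are
well-defined for partial sequences and keep accuracy independent of the
duration in speed's denominator. A sequence-level alternative (complete
error-free nine-press sequences over started sequences) is available via
`score_block(..., sequence_level=True)` for datasets that count whole
sequences; press-level is the default throughout.

## Learning curves and the plateau label

Training-block accuracy is fit per participant with

    accuracy(g) = a + b · ln(g)

over the global training-block index `g = (day−1)·6 + block` (closed-form
simple linear regression on ln g). Baseline and catch blocks present
different sequences and never enter the fit. The fit spans all training
days: the label concerns when the participant's accuracy stops improving,
which requires the full horizon. A participant needs ≥4 day-1 training
blocks to be labeled (curated real data can have missing blocks);
otherwise they are reported as unlabelable with a reason.

**Bending point.** The two-parameter log family has no intrinsic knee:
after normalizing the axes, the curve's shape is independent of `b`, so
purely geometric criteria (maximum curvature, normalized-knee rules) are
degenerate for it. The bend is therefore defined by a remaining-gain
threshold: the earliest block after which the fitted remaining improvement
falls below ε,

    bend = smallest g with  b · ln(N/g) < ε   ⇒   bend = N · e^(−ε/b),

clipped to [1, N], with N the total number of training blocks and
ε = 0.05 in absolute accuracy units by default (b ≤ 0 bends at block 1).
An ε of 0.05 means "less than five accuracy percentage points left to
gain"; the criterion is monotone in `b`, monotone in ε, closed-form
invertible (tested against a numeric root-finder), and configurable.
Participants whose bend falls within day 1 (`ceil(bend/6) = 1`) are
labeled **optimal**, the rest **suboptimal**.

## The stratifier and the likelihood-to-benefit map

Five raw features per participant — age in years, and speed and accuracy
in the baseline block and in the first training block — are standardized
(centered/scaled on the training set; necessary because years and
proportions live on very different scales), then expanded with every
degree-1 and degree-2 monomial (20 features). A linear maximum-margin
(support-vector) classifier separates the classes in the expanded space;
nonlinearity enters only through the expansion, keeping an explicit
hyperplane. Model selection runs 10 stratified Monte-Carlo 80/20 splits
(seeded; redrawn if a split misses a class) over the regularization grid
{0.01, 0.1, 1, 10, 100} and keeps the C with the best mean held-out F1
for the suboptimal (positive) class, then refits on all training data.
Only unstimulated (no-stimulation or placebo) participants may enter
training; verum participants are strictly predict-only.

Signed distances to the hyperplane (suboptimal side positive, normalized
by the weight norm) are mapped to probabilities with a Platt-style
sigmoid `p = 1/(1+exp(A·d + B))` fit by maximum likelihood on the
training distances with Platt's smoothed targets (keeps A finite when
the classes are separable). The intercept `B` is then absorbed into the
hyperplane offset, so the reported distance is measured from the
50%-probability boundary: `distance > 0 ⇔ probability > 0.5 ⇔ class =
suboptimal`, exactly. Both the full-training-set F1 (a feature-
separability index, since the same data trained the model) and the mean
held-out F1 are reported.

**Tiers.** Each predicted class is split at its training-set median
probability. In the optimal class, probabilities *below* the median are
`optimal-high` (furthest from the 50% boundary — closest to the optimum);
in the suboptimal class, probabilities *above* the median are
`suboptimal-low` (least efficient, largest expected benefit). A
probability exactly at the median joins the tier nearer 0.5.

## Dynamics and differential-effect statistics

The unit of behavioral change is the **dynamics ratio**: each training
block's score divided by the first training block's score, so every
series starts at exactly 1. Participants with a non-positive first-block
value are excluded with a logged reason. Group curves per tier×arm show
the per-block mean ratio with a 95% band from a seeded nonparametric
bootstrap (1000 participant resamples of the fitted `a + b·ln g` curve);
the analytic form of the source figures' bands is unstated, so a
bootstrap is used.

The omnibus model is `ratio ~ arm × time + (1 | participant)`, fit by
REML — statsmodels' `MixedLM` is the backend — with cell-means coding so
estimated marginal means are direct functions of the coefficients, and
Type-III style omnibus F tests. Degrees of freedom for 1-df contrasts
use the Satterthwaite recipe (numeric gradient of the contrast variance
against the inverse observed REML information), implemented in-package
because the backend provides neither Satterthwaite nor Kenward-Roger df;
the two methods agree asymptotically, and the output flags the method
used. Omnibus F tests use the mean per-row Satterthwaite df, flagged
`satterthwaite-mean`. Singular fits (intercept variance collapsing to
zero) degrade to fixed-effects inference with residual df, flagged.
The implementation is cross-checked against R's lmerTest on a fixture in
the test suite.

**Day-1 contrast.** "Day-1 change" is the mean ratio over day-1 blocks
g = 2..6 (block 1 is the reference and identically 1; including it would
only deflate the residual variance). The per-tier verum-vs-placebo
contrast is tested in a model restricted to that day-1 window with block
as the time axis (`ratio ~ arm × block + (1 | participant)`, g = 2..6):
ratio residual variance grows with the ratio level across days, so
pooling later days into one residual variance would miscalibrate the
day-1 standard error, and the within-day learning trend is fixed
structure, not noise. The contrast is the arm difference of EMMs averaged
over the window. Effect size `d` standardizes the estimate by the total
SD √(τ² + σ²).

**Family correction.** The four tier contrasts come from four independent
per-tier models, not one pairwise EMM family, so the studentized-range
(Tukey) machinery does not apply; the family correction is the Sidak form
`1 − (1−p)^k` — what emmeans itself degrades to for non-pairwise
families — and a singleton family is returned unadjusted. Power
statements use the adjusted p; type-I calibration of effect-free tiers is
read from the unadjusted per-tier p, because an adjusted p under a
partial null is deliberately conservative and cannot sit at α.

## Synthetic cohorts

Each simulated participant has a saturated-log accuracy curve
`clip(a0 + b·ln(min(g, x_p)), 0, 1)` — the simplest family in which
plateau timing is one controllable parameter (`x_p`, the plateau block) —
and monotone speed `s0 + speed_gain·ln(g)`. Baseline and catch blocks sit
at the sequence-unspecific level (a0, s0) with no trend, which makes
their exclusion from fits consequential and testable. Participants are
drawn from four archetypes matching the tiers (parameter ranges in
`TIER_ARCHETYPES`): optimal learners plateau within day 1 (x_p ≤ 4),
suboptimal learners plateau on later days (x_p ≥ 10) with larger total
gains and weaker baselines. Baseline ability (a0, s0) separates the
classes — the premise the classifier tests — and tier mixing weights per
age band keep every tier reachable from every band while skewing learner
quality with age. Ages are uniform within band (young 18–30, middle
50–65, older 66–80). The archetype ranges were calibrated once against
the bending criterion's noiseless closed form so that generative plateau
day and detected label agree exactly on the archetype grid (asserted in
tests).

**Noise.** Block accuracy is a mean over roughly 90·speed/accuracy ≈
150–180 presses, so by default its Gaussian noise SD is the binomial
floor √(p(1−p)/n) ≈ 0.027–0.038, truncated to [0,1] by resampling;
speed noise is likewise Poisson-derived, √(speed/90). Explicit SDs
override both (the label-recovery experiment deliberately runs at a
flat SD of 0.05, harsher than the default). With press-count noise the
injected stimulation effects below produce standardized day-1 effects
(d ≈ 1.5–2) of the same order as the study-scale contrasts; a flat SD
as large as the injected detriment would cap d near 0.9 and make the
detriment undetectable at any cohort size of this design.

**Injected stimulation effects** (verum arm only, accuracy only; speed
is never affected): suboptimal learners gain `suboptimal_day1_boost`
(default 0.10) from block 2 onward with their plateau pulled into day 1
(the boost persists across days — acquired skill does not reset — while
capping the plateau lets the placebo arm catch up later, reproducing the
converge-then-overtake pattern); optimal-high learners lose
`optimal_high_day1_detriment` (default 0.05) on day-1 blocks 2..6 only;
optimal-low learners are untouched. The raw-unit sizes are calibration
choices (the source analyses report only standardized statistics) and
are configurable.

Keypress streams can be generated per block: total press count is
Poisson at rate speed/accuracy, times are ordered uniforms over the 90 s
window, each press is correct with the target accuracy and expected keys
follow the repeating nine-digit sequence. Scoring these streams recovers
the block targets within binomial/Poisson sampling error (exact 1e-6
parameter recovery is asserted on the noiseless block path; discrete
counts quantize the keypress path at ~1/n).

## Validation experiments and problem sizes

`run_label_recovery` (200 participants, flat noise SD 0.05) measures
label/ground-truth agreement; `run_classifier_recovery` (60 unstimulated
participants) measures training-set and fresh-cohort F1;
`run_effect_recovery` (15 per arm per tier, 200 replicates) measures
per-tier day-1 power, sign agreement, and type-I calibration under the
global null. These sizes mirror the study scale (cohorts of 20–40 per
dataset) and keep the full simulation suite in the minutes range; every
report is reproducible from (experiment, seed).

## Known limitations

- The generator draws block scores directly from the latent curve; it
  does not model within-block press dynamics (chunking, inter-press
  intervals), fatigue, rest-day consolidation, or sequence-specific
  transfer between the baseline/catch and training sequences. Passing
  tests show the analysis recovers structure *of this generative form*;
  real data can violate it (non-log curves, non-monotone speed).
- The bending-point criterion is this package's operationalization; other
  changepoint definitions (segmented regression, Bayesian online
  changepoint detection) are deliberately out of scope.
- Age enters the classifier in years; entering band codes instead would
  change the geometry.
- Kenward-Roger df are not implemented; Satterthwaite is used throughout
  (flagged), and omnibus multi-df denominators are approximate.
- The Sidak family correction treats the per-tier contrasts as
  independent; they are, by construction, in the synthetic design, but
  tiers estimated from a shared classifier on real data would be weakly
  dependent.
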