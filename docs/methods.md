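# Methods

This note documents the models implemented in `graphotrace`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Stimulus synthesis and the shape-space metric

Stimuli are radial-frequency contours: a base circle modulated by a small
set of cosine harmonics,

    r(θ) = R · (1 + Σₖ Aₖ · cos(kθ + φₖ)),

which produces closed, simple ("bumps and dimples") amoeboid outlines as
long as r(θ) > 0 everywhere — the only validity condition enforced
(`InvalidProfileError` otherwise; a large Σ|Aₖ| is acceptable when phases
oppose). Contours are sampled at 256 arc-length-uniform vertices from a
dense polar evaluation, centred on the vertex centroid, and scaled so the
largest caliper extent is 4.9 cm (≈ 7° at the 40 cm viewing distance).
Coordinates are planar centimetres, y up, and contours are stored with the
first vertex repeated last.

Similarity between two contours is the root-mean-square difference of
their centroid-referenced radial profiles, minimised over cyclic rotation
of the sampling start index. The rotation minimum makes the measure
independent of where sampling begins; it is a true metric (the quotient of
the Euclidean RMS metric by the cyclic-shift group), which the test suite
verifies by exhaustive triangle-inequality checks on the generated set.

### The equidistant ring

The 8 stimuli must satisfy two constraints: the seven consecutive
distances d(i, i+1) are equal, and d(8, 1) = 3 steps. These are jointly
infeasible on a *straight* morph segment in harmonic-amplitude space,
because the RMS metric is additive along a line (the end-to-end distance
would be ~7 steps). The construction therefore places the shapes on a
**closed loop**: a circle in amplitude space centred on a base amplitude
vector, spanned by two random orthonormal directions, with the harmonic
frequency set {3, 4, 5, 6, 7}, base amplitudes ≈ 0.05 and loop radius
0.06 (all fractions of the base radius — large enough to make shapes
visibly different, small enough that every loop point is a valid simple
contour).

For points on a circle the Euclidean chord geometry gives a closed-form
initial angular spacing α from sin(7α/2) = 3·sin(α/2). Because arc-length
resampling, caliper rescaling and the rotation minimum slightly distort
the metric, the final positions are found numerically: an inner pass
places each shape by bisection on its loop angle so its distance to the
predecessor equals the current step estimate, and an outer root-finding
pass adjusts the step so the measured 8→1 distance equals exactly three
steps. Construction fails loudly (with diagnostic distances) if the
1% relative tolerance cannot be met; at the defaults it converges to ~1e-6
relative deviation in under a second and is fully determined by the seed.

The loop construction, the metric, and the specific parameterisation are
this package's own reconstruction of the stimulus-synthesis idea (the
original procedure is not published in detail); nothing downstream depends
on more than the ring's distance structure.

## Discrimination scoring

Ring distances live on the weighted cycle with unit edges between
consecutive shapes and a 3-step edge between 8 and 1 (so e.g.
d(1,5) = 4 via the short arc and d(8,2) = 4 via the wrap edge).

*Accuracy* is the hit proportion of a 64-trial block. *Relative distance
error* is the trial-mean ring distance between target and choice divided
by 2.375 — the expectation of that distance for a uniform random target
and uniform random choice (computed by enumerating all 64 pairs). Hits
contribute distance 0 and are included in the mean, which keeps the two
measures jointly interpretable: perfect matching scores 0, chance-level
responding ~1, and a systematically far-choosing responder can exceed 1
slightly. This normalisation is a declared stand-in — the original
normalising constant is not published — so absolute error levels from
other parameterisations are not directly comparable; orderings and
baseline-adjusted differences are.

Baseline adjustment is per participant: Δaccuracy(t) = accuracy(t) −
accuracy(pre), and Δerror(t) = error(pre) − error(t), signed so that
positive always means improvement.

## Trace kinematics

*Duration* runs from the first pen-down sample to trial completion. A
terminal movement stop — a trailing segment whose path advance stays below
0.05 cm and that lasts longer than 200 ms — is trimmed, because trial
completion is defined by movement stop or stylus lift and a rest before
lifting should not count as tracing time. (The 200 ms floor keeps the last
sample of a continuously moving trace from being misread as a stop.)

*Validity* mirrors the acquisition abort rules: any window longer than
400 ms over which the pen path advances less than the 0.05 cm stillness
threshold invalidates the trial (`pause`), as does exceeding the 15 s
limit (`timeout`). The stillness threshold is a package choice; only the
400 ms limit is given by the acquisition protocol.

*Area error* treats both curves as closed polygons (an open trace is
closed endpoint-to-start; residual gaps are small because tracing is one
full cycle) and returns the area of the symmetric difference of their
enclosed regions, via `shapely`. This is robust to the trace crossing the
template, unlike an integrated radial deviation; self-intersecting trace
polygons are repaired by even–odd region construction. The implementation
is validated against the annulus closed form π|s² − 1| and the general
scaling law |s² − 1|·area.

*SPARC* is computed in the published form: speed is obtained by resampling
pen positions to 100 Hz, zero-phase low-pass filtering at 10 Hz
(2nd-order Butterworth, forward–backward), and central differencing; the
magnitude spectrum (FFT zero-padded to the next power of two ≥ 4× the
length) is normalised by its DC value; the band runs up to the last
frequency ≤ 10 Hz at which the normalised magnitude still reaches 0.05;
and the score is the negative arc length of the spectrum over that band
with the frequency axis normalised by the band width. The resampling rate,
cutoff, threshold and padding are the SPARC literature defaults, declared
here rather than inferred (the acquisition-side values are unpublished).
DC normalisation makes the score invariant to speed amplitude scaling; a
minimum-jerk profile scores ≈ −1.41 (pinned against a fine-quadrature
oracle in the tests).

## The synthetic cohort

**Observer model.** Choices follow
p(j | target) = (1 − λ)·softmax_j(−β·ringdistance(target, j)) + λ/8 —
the simplest kernel consistent with nearer ring neighbours being more
confusable. It is a modelling stand-in, not a claim about participants'
decision process. The lapse rate defaults to λ = 0.01, which keeps the
attainable accuracy range (12.5%, 99.1%) comfortably around the clip
bounds below. β is recovered from a target accuracy by bisection on the
exact expected hit rate (uniform target average), to 1e-6.

**Learning injection.** Each participant draws a baseline accuracy and
pre→post / pre→retention accuracy changes from group-level truncated
normals (redraw, then clip to [0.13, 0.98] — observed post-training
accuracies spanned roughly 45–92%, so the bounds are rarely active). The
group defaults carry the published statistics: Experiment 1 uses the
pooled baseline 45.63% ± 8.30% for all four groups (no baseline group
difference was reported) with per-group Δs (post: 19.8/21.1/24.1/17.7 %;
retention: 24.1/21.2/26.2/13.4 %), whose averages are the pooled +20.7%
and +21.2%; Experiment 2 uses baselines 51.4% ± 8.9% (non-dominant) and
42.1% ± 7.8% (dominant) with the corresponding published Δs. Retention is
drawn independently rather than as post plus drift, matching how the
group tables are reported.

**Schedules.** 64-trial assessment blocks (each shape a target 8 times,
shuffled); 200-trial training sessions (8 × 25, shuffled); a 40-trial
familiarization block (8 shapes × 5, out-of-set shapes) containing 16
catch trials, two per shape, with the 5 mm / 1,200 ms width-change
parameters carried as metadata. The familiarization block length is a
package choice — only its catch content (16, two per shape) is specified
by the protocol.

**Trace generator.** The pen follows the template from a random start
point and direction, at speed v(t) = v̄·(1 + a·sin(2πft + φ)), displaced
along the local outward normal by periodic correlated noise (white noise
circularly convolved with a Gaussian kernel of 1 cm correlation length,
scaled to the configured SD). Hand defaults: dominant v̄ = 5 cm/s, noise
SD 0.09 cm, ripple 0.15 at 3 Hz; non-dominant v̄ = 2.5 cm/s, noise SD
0.20 cm, ripple 0.35 at 4 Hz. Day-2 multipliers: dominant ×1.3 speed,
×0.65 ripple, ×1.0 noise; non-dominant ×1.15, ×0.85, ×0.75. These values
were chosen once to reproduce the *directional* published contrasts — the
dominant hand quicker, spatially more accurate and smoother; across
sessions the dominant hand speeds up and smooths more but does not improve
in spatial accuracy, while the non-dominant hand improves on all three —
with magnitudes in a realistic range for a ~14 cm template perimeter. No
published trace-level values exist to calibrate against.

**Randomness.** One master seed; per-participant and per-block substreams
are derived as `default_rng([seed, participant, block])`, so module-level
use and full pipeline runs agree and all outputs are byte-reproducible.

## Statistics

The mixed ANOVA computes every sum of squares by explicit marginal-mean
decomposition (between-subjects split into Group and subjects-within-
groups; within-subjects into Time, Time×Group and the within error), valid
for the balanced designs this pipeline produces; unbalanced group sizes
are supported, missing cells are not (they raise, naming the
participants). Partial η² uses each effect's own error term. Mauchly's W
is computed from the pooled within-group covariance of an orthonormal
within-subject contrast basis, with Box's chi-square approximation
including the second-order series term; Greenhouse–Geisser ε =
(Σλ)²/((k−1)Σλ²) on the same eigenvalues, clipped to [1/(k−1), 1]. The
correction is applied when Mauchly's p < 0.05. Note that GG correction is
guaranteed conservative only when F is clearly above 1; near F = 1 the
corrected p can be marginally smaller.

Post hocs are Bonferroni-corrected paired t-tests; Cohen's d is reported
both as d_z (mean difference / SD of differences) and d_av (mean
difference / average level SD), with d_av the headline convention for
repeated measures (the two can differ substantially when levels are
highly correlated).

Two-sample comparisons run Brown–Forsythe (one-way ANOVA on absolute
deviations from group medians) first and route to Welch's t when it
rejects at 0.05, otherwise the pooled Student t; Cohen's d uses the pooled
SD in both cases.

The JZS Bayes-factor t-test integrates the Cauchy-prior (r = √2/2)
marginal likelihood in its g-representation by adaptive quadrature and
returns BF01. The Bayesian mixed ANOVA uses the BIC approximation
BF01 ≈ exp((BIC_model − BIC_null)/2) over the model set {null, Time,
Group, Time+Group, Time×Group}, each fit by maximum likelihood as a
compound-symmetric (random-intercept-per-participant) Gaussian model with
the variance pair optimised directly on the log scale and the fixed
effects profiled out by GLS. BIC-based Bayes factors rank models reliably
but their magnitudes are not calibrated to any particular prior, so only
model ordering — not BF magnitude — is meaningful for comparison with
other software.

## What passing tests do and do not show

The generator reproduces, by construction, the group-level accuracy
distributions it is configured with; parameter-recovery tests therefore
validate the *pipeline* (calibration, trial simulation, scoring,
baseline adjustment are jointly unbiased), not the behavioural theory.
Real data differ in ways the simulator deliberately omits: reaction
times carry no signal, lapses are stationary, there are no session or
fatigue effects within a block, trace noise is stationary along the
contour, catch-trial behaviour is not modelled, and the yoked visual
groups see schedules only as metadata. Directional kinematic contrasts
(hand and session effects) are reproduced in ≥95% of seeded replicate
cohorts, but their effect magnitudes are generator choices.

## Problem sizes and numerics

Default test-suite problem sizes: 20-seed × 40-participant recovery runs,
100 replicate cohorts with one trace per shape per hand × session cell,
and 2,000-replicate type-I-error simulation at the 4 × 10 × 3 geometry —
all chosen as the smallest sizes at which the binomial/3-SE acceptance
bands are informative. Degenerate inputs raise typed exceptions
(`DegenerateInputError`, `InfeasibleTargetError`, `UndefinedSmoothnessError`)
rather than returning NaNs, except that invalid traces carry NaN metrics
by design so session means can exclude them. Ties in the adaptive SPARC
band resolve to the last qualifying frequency bin; bisection tolerances
are 1e-6 throughout.
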