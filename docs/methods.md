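# Methods

This note documents the models and procedures implemented in
`tepstates`, the choices made where the design was genuinely open, and
what the synthetic validation does and does not establish.

## Data model and timing

A record is one subject's averaged TMS-evoked potential for one cell of
the 2 (pulse waveform) × 3 (current direction) within-subject design: a
channels × timepoints matrix in µV on a fixed 74-channel 10-10 montage,
time-locked to the TMS pulse. Time is in milliseconds relative to the
pulse; the epoch spans −200 to 400 ms. Analysis windows are half-open
`[start, end)`; the per-component peak windows are closed intervals
because the published component tables tile the axis with touching
decimals (…24.9 / 25…). Down-sampling from acquisition rates to 960 Hz
uses integer-stride decimation when the rates are commensurate (the
4800 → 960 case is an exact factor 5; evoked inputs are low-pass
filtered far below the target Nyquist), polyphase resampling otherwise.
The default analysis window is 5–400 ms; 0–400 ms is supported through
the same window parameter, since both conventions appear in practice.

## Peak analysis

Each component (N15, P30, N45, P60, N100, P180) is measured on the
unweighted mean of its four ROI channels as the signed extremum —
minimum for negative, maximum for positive components — within its
closed time window, boundary samples eligible, earliest sample winning
ties. A windowed extremum rather than a local-peak search is deliberate:
component windows are defined not to overlap their neighbours, and
individual subjects may lack a component or show inverted polarity, in
which case the extremum (possibly "wrong-signed") is still the defined
measure. Outlier screening flags a subject for a component when
amplitude or latency in any condition deviates from that condition's
group mean by strictly more than 2.5 SD, in a single pass (no iterative
re-screening); exclusion applies to the whole component across
conditions. Normality transforms (none, √, log₁₀, inverse; shifted into
domain when needed, shift recorded) are scored by Shapiro–Wilk W, the
highest W winning; if none reaches p > .05 the result signals the
robust-statistics path.

## Microstate analysis

**Normalisation.** Each record is divided by its mean GFP over the
analysis window (mean-GFP rather than timepoint-wise normalisation:
dividing each timepoint by its own GFP would flatten the GFP series and
destroy the GFP²-weighting that the explained-variance measure relies
on; the timepoint-wise variant would also amplify noise-only periods).

**Topographic consistency test.** Per condition, the observed statistic
at each timepoint is the GFP of the across-subject mean map; surrogates
permute each subject's channel order independently (destroying shared
topography while preserving each subject's amplitude spectrum across
channels), re-average and recompute the GFP; 5000 permutations by
default with add-one p-values, so p is never zero.

**Clustering.** The segmentation is a modified k-means on the
concatenated per-condition grand-average maps: label each map with the
best-correlated template, refine each template from its assigned maps,
iterate to label stability; 250 restarts, the restart with the highest
GEV retained; an emptied class reseeds from the worst-fit map. Polarity
handling follows the evoked-potential convention by default
(`signed`): labelling uses the signed spatial correlation and the
update is the normalised mean of the assigned raw maps. A
polarity-indifferent mode (`ignore`, the resting-state convention)
labels by |r| and updates each template as the first principal
component of the class's GFP²-weighted map scatter — the optimal
template for a fixed labelling, which makes that variant a monotone
ascent on GEV and lets a brute-force enumeration over all labelings
serve as an exact oracle on tiny instances.

Seeding is k-means++-style in correlation distance: the first seed map
is drawn with probability proportional to GFP², subsequent seeds with
probability ∝ GFP² · (1 − max |r| to the seeds already chosen)².
Evoked data spends two-thirds of its samples inside the longest-lived
late topography, so uniform seeding practically never covers all six
classes and even hundreds of restarts stay trapped in merged-class
local optima; dissimilarity-weighted seeding fixes this while remaining
a random draw of data timepoints, and the restart-and-retain-best-GEV
procedure is unchanged.

**Map-count selection.** Split-half cross-validation: per iteration the
subjects are split in half at random, templates are fit on the learning
half's condition grand-averages for each K in 3…12, and scored by the
GEV they attain on the test half's grand-averages; 50 iterations, the
curve averaged, and the selected K is the smallest within 1 % of the
curve maximum ("first K on the plateau"). The half-split and the 1 %
plateau tolerance are conventions chosen here; the CV restart budget is
reduced (restarts = 6, capped iterations) since the curve is an
average over 50 × 10 fits.

**Backfitting and features.** Each subject × condition record is
labelled with the group templates (deterministic, ties to the lowest
class index). Per class: duration = labelled samples × Δt; AUC = sum of
GFP over labelled samples × Δt; onset = time of the first labelled
sample, absent if the class never occurs. Durations sum to the labelled
span and AUCs to the total GFP area exactly. Two optional label filters
exist and default off: a minimum-duration filter that merges label runs
shorter than a threshold into the better-fitting neighbour run
(isolated one-sample labels in noisy data are sensor noise, not
microstate visits), and an unassignment rule that marks timepoints
whose best |r| stays below 0.5 as belonging to no class. The onset
analyses in the validation suite enable both (minimum duration 6 ms),
because a single noise-driven early label otherwise redefines a class's
onset.

**Subject screening.** Each subject is summarised by the concatenation
of their six condition-average maps over the window; the squared
Mahalanobis distance is computed leave-one-out — against the mean,
PCA subspace (≥ 90 % variance, at most n − 2 dimensions) and
covariance of the other subjects — and referred to the exact
scaled-F threshold for a new observation at the 0.99 quantile. The
all-in sample distance is bounded by (n−1)²/n, which a χ² quantile can
exceed at realistic n; the leave-one-out distance is unbounded and
makes gross deviants (e.g. a subject with scrambled channels)
stand out maximally. A caveat the validation makes explicit: with a few
dozen subjects in a very high-dimensional topography space, distances
concentrate and the nominal 1 % marginal false-flag rate of the
threshold is not reached — the screen in practice flags (essentially)
only gross deviants, which is the safe direction for a subject-
exclusion rule.

## Statistics

The 2 × 3 repeated-measures ANOVA is computed from the sums-of-squares
decomposition, with Mauchly's test (orthonormal-contrast form,
χ² approximation) for the three-level factor and the interaction, and
Greenhouse–Geisser correction applied when Mauchly rejects at .05;
effect size is partial eta squared. Tukey post-hocs refer the paired
t statistics to the studentized-range distribution (q = |t|·√2, k
groups, n − 1 df); paired Cohen's d = mean difference / SD of
differences. The robust one-way repeated-measures ANOVA uses 20 %
trimmed means with Yuen-scaled Winsorized covariances; its F reduces
exactly to the classical repeated-measures F at trim = 0, and its
degrees of freedom carry a Huynh–Feldt-type sphericity adjustment
estimated from the Winsorized covariance with the effective (post-trim)
sample size; pairwise ψ contrasts use Yuen paired standard errors.
ANCOVA of the direction effect partials out subjects with fixed
intercepts and adjusts for the TMS-intensity covariate in an OLS
type-II table.

Microstate onsets are modelled with a gamma family and identity link —
onsets are strictly positive with spread growing with latency, and
condition effects on onsets are additive (a time shift, not a time
scaling) — with sum-coded subject intercepts absorbing between-subject
latency offsets, and class, stimulation condition and their interaction
as fixed effects. Inference is by Wald tests on the sum-coded term
blocks (type-III style); the statistic is referred to F(df, residual
df) rather than χ²(df), the finite-sample correction without which the
χ² reference is liberal at ~60 parameters for ~970 observations.
Within-condition class-pair contrasts (15 pairs × 6 conditions = 90)
are Benjamini–Hochberg corrected over that fixed family; the swap
report lists class pairs whose significant contrast changes sign
between conditions. Missing onsets are dropped listwise (gamma
support), with the count reported. If the identity-link fit fails or
produces non-positive fitted means, the model refits with a log link
and flags the fallback. With complete balanced designs the fixed
subject-intercept formulation gives essentially the same fixed-effect
contrast inference as a random-intercept model, without the fragility
of fitting a non-canonical-link gamma mixed model.

BH adjustment is the standard step-up with enforced monotonicity; a
declared family size larger than the supplied set treats the absent
members as p = 1.

## Synthetic data

A simulated record is a sum of time-gated topographies:
`data[:, t] = g(t − jit_s) · a_s · √n_ch · u_{class(t), s} + ε`, with
`g` a non-negative GFP envelope (Gaussian bumps at 15/30/45/60/100/180
ms, widths and 2–4 µV peaks growing with latency as real TEP components
do), `a_s` a lognormal(σ = 0.2) subject amplitude scale, `u_k` smooth
(spatially low-passed over electrode positions) zero-mean unit-norm
template maps with pairwise |r| ≤ 0.5, and ε iid Gaussian sensor noise.
The √n_ch factor makes the noise-free GFP equal `g(t) · a_s` exactly,
so the envelope is specified directly in µV of GFP. Latency
variability has two parts: a per-subject time shift (N(0, 3 ms) by
default) and a per-segment-boundary multiplicative perturbation
(lognormal, σ = 0.05 by default) making later transitions
proportionally more variable — the pattern real evoked latencies show —
and keeping each class's onset variability independent across classes
and conditions. Smooth random fields stand in for dipolar forward
models deliberately: clustering only ever sees topography vectors, so
physical realism adds nothing to the test.

Bundled scenarios: `clean6` (27 subjects, six maps tiling 5–400 ms,
sensor SNR ≈ 5), `swapAB` / `swapAB_null` (classes 1 and 2 in
60-ms slots from 20 ms, order-swapped between waveforms or not;
envelope floor of 1.5 µV so topography is present throughout, σ = 0.10
latency scaling ≈ 8–10 ms onset jitter at the swapped classes; the
first 15 ms of the window deliberately carry no signal so no class's
onset is pinned to the window edge, keeping onsets on strictly
positive, boundary-free support as the gamma model assumes),
`deviant1` (clean6 with one channel-scrambled subject), and `nullflat`
(pure sensor noise, for calibration).

What the generator does **not** emulate: volume-conducted spatial
correlation of sensor noise, trial-limited averaging noise, TMS decay
or muscle artefact residues, per-subject electrode digitisation error,
and gradual (rather than switched) transitions between sources. Tests
passing on this generator therefore establish the correctness and
calibration of the *algorithms*, not the field validity of microstate
assumptions on real TEPs.

## Validation problem sizes

The validation suite (`tepstates.validation`, exercised by
`tests/test_acceptance.py` and `scripts/acceptance.py`) uses: template
recovery and noiseless exactness at full scale (27 / 3 subjects, 250 /
40 restarts); map-count selection over 20 repetitions at 480 Hz with a
reduced CV restart budget; TCT calibration and power with 5000
permutations (20 subjects); the exhaustive clustering oracle on 100
random 3-channel × 8-timepoint instances; swap detection over 50
full-chain simulations and the interaction null over 300 (test) / 200
(script) full-chain repetitions; 1000-replicate nulls for the
repeated-measures tests; and 100 (test) / 60 (script) screening runs.
The map-count scenario carries no latency jitter: split-half validation
of the class count presumes the group shares segment timing, and jitter
smears transitions into genuine intermediate topographies that inflate
the apparent count (the curve then climbs past the true K; this
behaviour is reproducible with the generator and worth knowing about
when interpreting real-data map counts).
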