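# Methods

`forageseq` implements the analysis pipeline for a hidden-zone foraging
task in a 100-cm circular arena: mice alternately collect a *foraging*
reward (visit one zone of each of three hidden types A/B/C, reward after a
0.6–2-s delay upon entering the last one) and a *goal* reward (dwell 1 s in
a hidden goal zone), while CA1 units, one LFP channel and position are
recorded. The package analyzes behavior (stereotyped foraging sequences),
place coding, theta-phase coding and multi-covariate selectivity, and ships
a synthetic-session generator with complete ground truth so every stage has
a parameter-recovery test.

## Conventions

Arena center at the origin; positions in cm; angles in degrees,
counterclockwise from +x, in [0, 360); time in seconds; all bins half-open
[lo, hi). Tracking (nominal 25 Hz) is linearly interpolated to a uniform
100-Hz timeline. Speed and heading are differentiated from a
Gaussian-smoothed (50-ms SD) copy of the positions so camera jitter does
not dominate the derivative; the exported positions stay unsmoothed, which
makes resampling idempotent on already-100-Hz input. Frames slower than
2.5 cm/s, or interpolated across tracking gaps longer than 200 ms, are
excluded from analysis.

Unit classification: a unit is a putative pyramidal cell when its mean rate
is below 5 Hz, its burst index exceeds 2 and its autocorrelogram has a
prominent early peak. The burst index is not standardized in the
literature; here it is the mean autocorrelogram value at 3–6-ms lags
divided by the 200–300-ms baseline mean (1-ms bins), and "prominent early
peak" means the 3–18-ms maximum reaches twice the baseline mean. Units
with fewer than 50 spikes stay unclassified.

## Behavior: sequence templates

Trials run from one goal reward to the next; the foraging trajectory ends
at the entry into the last zone before the foraging reward and the
goal-directed trajectory runs from the foraging reward to the first goal
zone entry. Performance metrics: rewards per minute, median foraging path
length, and median goal-directed path length normalized per trial by the
straight-line distance between its endpoints.

Each foraging trajectory becomes a complex-valued map on a 5-cm grid:
movement directions are discretized to 20° bin centers, consecutive
same-bin samples are collapsed (in chunks of at most 200 ms — the source
procedure does not say what happens to longer dwells, so they contribute
one unit vector per 200-ms chunk) to unit vectors at their circular mean,
and the unit vectors landing in a spatial bin are averaged into
M = l·e^{iθ} with l ≤ 1. The distance between two trials is

    d(i, j) = 1 − Re⟨M_i, conj(M_j)⟩ / (‖M_i‖·‖M_j‖)

over the bins visited in both trials (range [0, 2]; 0 identical, 1
orthogonal, 2 antiparallel). Pairs with no common coverage cannot be
dropped from an agglomerative linkage, so they enter at the maximal
distance 2 — equivalent in effect, since such trials never merge early.
Average-linkage clustering is cut at the threshold in [0.1, 0.4] (0.01
steps) that maximizes the number of clusters with more than 30 member
trials (ties go to the lowest threshold); each such cluster's mean map is
a sequence template. A trial is a *sequence trial* when its Pearson
correlation with some template — over the concatenated real and imaginary
parts of commonly visited bins, mean-centered (an uncentered variant is
available via `centered=False`) — exceeds 0.6. Dark-condition trials are
matched against the light templates.

## Place fields

Rate maps divide a spike-count map by an occupancy map on the 5-cm grid,
both restricted to bins visited on at least 3 trials and smoothed with a
5-cm-SD Gaussian (masking precedes smoothing; smoothing the two maps
separately before division avoids amplifying division noise). Spatial
tuning strength is the sparsity 1 − (ΣR)²/(N·ΣR²): 0 for a flat map,
1 − 1/N for a one-hot map, scale-invariant.

Significance is shuffle-based: the spike train is circularly shifted by a
uniform random delay in [5 s, span − 5 s] 500 times (count and inter-spike
intervals preserved); the observed strength must strictly exceed the
linearly interpolated 95th percentile of the shuffled strengths.
Predictive power: ten contiguous held-out blocks, each predicted from the
rate map fit on the remaining 90% and scored by Poisson likelihood
against the constant-mean prediction; the ratio statistic 2ΔLL is referred
to a chi-square with (valid bins − 1) degrees of freedom. The smoothed map
has far fewer effective parameters than bins, so this gate is
conservative; the labeled-population recovery test is the calibration
guard. Stability is the Pearson correlation of two sessions' maps over
commonly valid bins, significant when it exceeds the 95th percentile of
pairwise shuffle-vs-shuffle correlations. A cell is a place cell when all
three criteria pass; light/dark contrasts additionally require
significant S1–S2 and S2–S5 stability, so drifting cells cannot
masquerade as dark-induced changes.

Held-out rates (place-field CV and GLM CV alike) are floored at 1% of the
training mean rate: bins occupied in training but without training spikes
sit at the likelihood boundary (log-rate → −∞, coefficient capped), and a
single held-out spike there would otherwise dominate a model comparison
by an amount set by the cap, not the data. The common floor keeps the
held-out likelihood finite and model-independent in those bins.

## Theta

The LFP (1 kHz) is band-passed at 6–9 Hz with a zero-phase third-order
Butterworth (forward–backward, so filter delay cannot bias phase); local
maxima closer than 60 ms to the previously retained peak are discarded
sequentially, and phase is the elapsed fraction of the surrounding
inter-peak interval (0° at each retained peak; peak = 0° is the adopted
sign convention). Phase tuning divides circularly smoothed (20°-SD
Gaussian over 18 × 20° bins) spike-count and occupancy histograms; the
modulation index is the amplitude of the closed-form least-squares
sinusoid divided by the curve mean, tested against the same 500-shuffle
circular-shift null. The smoothing attenuates a cosine of depth m to
m·exp(−σ²/2) ≈ 0.94 m at σ = 20°; recovery tests check against the
attenuated value.

Place-field boundaries for precession: bins whose rate exceeds the
per-bin 95th percentile of the shuffle maps form the significant set;
4-connected components are labeled and only the largest-area subfield is
analyzed, bounded by the convex hull of its bin centers (bin corners when
fewer than three non-collinear centers exist), with a rate-weighted
center of mass. The position of each in-field spike is projected on the
running direction and normalized by the distance from the center of mass
to the hull along that direction ("pdcd": −1 at entry, 0 at the center,
+1 at exit; a raw-cm variant is available through the same geometry
helpers).

The precession slope maximizes the mean resultant length of
φ_k − 360·s·d_k over s ∈ [−0.5, 0.5] cycles per pdcd unit (0.01 grid plus
bounded refinement). Physiological precession advances less than one
theta cycle per field traversal, and a traversal spans pdcd −1…+1, hence
the ±0.5 bound; widening the search acts like multiple testing and
measurably inflates the null (11% false positives at ±2 versus 4% at
±0.5, nominal 2.5%). The circular–linear correlation ρ and
z = ρ·sqrt(S20·S02/S22) (S_ij = Σ sin^i(φ−φ̄)·sin^j(θ−θ̄), θ_k = 2π|s|d_k)
give p = 1 − erf(|z|/√2). A cell precesses significantly when p < .025,
the phase coverage 360·|s|·(max d − min d) exceeds 45°, and at least 30
spikes fall inside the field. Clean-run selection keeps contiguous
in-field traversals with min speed > 5 cm/s, mean speed > 10 cm/s,
circular SD of heading < 30° and min |pdcd| < 0.2.

## Poisson GLM and forward selection

Spike counts per 10-ms frame follow N = exp(a0 + B·X) with one-hot blocks
for position (5-cm bins on the place-field mask), direction (20° bins)
and speed (5-cm/s bins, 0–40, top bin open). All candidate models share
one sample set (valid frames, masked position bins, defined heading).
The likelihood is concave; the solver is a dense Newton iteration whose
gradient and Hessian are assembled by `bincount` over the per-sample bin
codes (no explicit design matrix), with one reference bin per covariate
pinned at zero for identifiability — the mean-centering in the
tuning-curve conversion absorbs the gauge. Single-covariate fits use the
exact closed form (per-bin empirical means). Convergence is declared at a
relative log-likelihood change of 1e-6 (absolute ~1e-3 for typical
sessions, orders of magnitude below any decision threshold); the solver
matches an external IRLS implementation to 1e-11 in the linear predictor
at tight tolerance, and satisfies the canonical-link identity
Σ fitted = Σ observed.

Forward selection: the best single covariate by total held-out likelihood
(10 contiguous folds); candidate extensions are tested with the classical
likelihood-ratio test on the fitted likelihoods (df = added coefficients),
Bonferroni-corrected by the number of extensions considered, and among
significant extensions the best held-out one wins; the full model is then
tested against the chosen two-covariate model. The final model must beat
the constant-mean model both on held-out likelihood and by the LR test,
otherwise the cell is "none". Two design notes, both measured during
development: testing 2ΔCV-LL itself against the chi-square double-counts
complexity (held-out likelihood already pays ≈1 unit per coefficient) and
has almost no power for weak covariates; and the plain Wilks gate against
the constant model false-validates ~25% of flat cells because the best of
three candidates is picked before the 5% test — the held-out conjunction
at that gate alone restores calibration without costing power. Ties break
P > D > S.

Coefficients convert to tuning curves y_k = α·e^{X_k}/δt with
α = e^{a0}·∏_{j≠k} e^{mean X_j} (unweighted bin means), smoothed after
exponentiation (5 cm / circular 20° / 5 cm/s), and to tuning strengths by
the same sparsity index. The light/dark contrast Δ = strength_dark −
strength_light uses the covariate set selected in the light condition for
both conditions and only cells passing the stability gates.

## Synthetic sessions

The generator emulates the task, not the biophysics. A heading-relaxation
walker (per-leg cruising speed from a truncated normal, mean 15 cm/s, SD
50%, OU fluctuation — near-constant speed would leave speed bins
unoccupied and carry no speed information) runs trials that are
sequence-following (waypoint path through one template's zones, low
steering noise) with the configured probability, otherwise random
foraging (random zone choice and order, random via-points, high noise).
Rewards follow the task rules (three zone types → delayed foraging
reward; 1-s goal dwell → goal reward); a leading goal dwell makes every
simulated trial a complete, labeled inter-goal-reward interval. The
default layout has one central type-A zone, three type-B and three
type-C zones (8-cm radius, 28-cm ring) and a goal zone at the wall.

The LFP is a theta-band carrier with slow amplitude modulation, white
noise (SD = amplitude/SNR, default SNR 5) and instantaneous-frequency
wander (SD 0.3 Hz, ~1-s correlation, clipped to 6–9 Hz). The wander is
load-bearing: against a perfectly periodic theta, a circular time-shift
preserves every spike's phase and the shuffle test for phase tuning would
be degenerate. Real theta drifts; the wander is what makes that shuffle a
valid null.

Spike rates are multiplicative: a 2-D Gaussian place field (or a constant
for untuned cells) × cosine direction gain (1 + g_D·cos) × linear speed
ramp × theta gain (1 + m·cos); precessing cells advance the preferred
phase by `precession_slope` degrees per unit of true pdcd (position
projected on heading, normalized by twice the field SD). Dark sessions
multiply g_D by `dark_gain_direction` and shrink the place field toward
its mean by `dark_gain_position`. Spikes are drawn by thinning a
homogeneous Poisson process at the peak rate — exact for the
piecewise-constant (10-ms) intensity. One `numpy` generator seeds
everything; sessions reproduce bit-exactly, and the pipeline fans out
child seeds with a counter-based scheme so adding cells does not perturb
existing ones.

What the generator does not emulate — and hence what passing tests do not
show about real data: no ripples/replay, no theta sequences beyond
single-cell precession, no electrode drift or sorting errors, no
reward-stimulation artifacts, no inter-animal variability, and covariate
correlations only insofar as the trajectory induces them. One such
induced correlation is real and visible in the results: within a 5-cm bin
the place-field gradient correlates with heading, so very-high-count
cells can pick up a small genuine direction term the binned position
model cannot absorb.

## Problem sizes in the test suite

Recovery and calibration runs use sizes chosen to estimate each rate with
useful precision: 1000 random map pairs for the metric axioms; 200
untuned cells × 500 shuffles on a ~4-min null session for shuffle
calibration (calibration does not depend on session length); 50 + 50
labeled cells on a 12-min session for place-cell recovery; 100 cells per
covariate category sharing one ~24-min trajectory (the span of the two
pooled sessions used for field estimation) for forward-selection
recovery, with fields within 25 cm of the center, widths 9–13 cm and
peaks 8–14 Hz (well-sampled fields); 300 null cells for the precession
false-positive rate; cohorts of 100–150 trials for sequence-fraction
recovery (a template needs more than 30 member trials, so a 0.3-fraction
cohort needs ≥120 trials for recovery to be well-posed).
`scripts/acceptance.py` recomputes the same quantities at somewhat
smaller sizes and prints them as JSON.

## Known limitations

- The sequence-template threshold search optimizes cluster count, not
  membership purity; cohorts whose true fraction times trial count is
  near the 30-trial template floor recover a fraction of 0.
- The CV predictive-power chi-square (df = bins − 1) is conservative by
  construction; its guard is the labeled recovery test, not analytic
  calibration.
- The precession p-value is asymptotic; with the slope re-fitted under
  phase shuffling the null is slightly left-shifted (a selection effect
  inherent to resultant maximization), which is why the significance
  level, coverage and spike-count gates are applied jointly.
- GLM category labels are exact-set labels; a cell with a genuine but
  sub-threshold covariate is assigned the smaller model by design.
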