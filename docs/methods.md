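# Methods

`filmbend` analyzes the bending of a chemo-mechanically actuating polymer
filament (a polyaniline–cellulose-acetate composite strip) suspended in the
headspace above acetone/ethanol/water mixtures. The pipeline has five stages:
a synthetic experiment generator, a classical row-scan video tracker, a
shape-ensemble PCA, per-trial transient-response fits, and linear calibration
models between solution composition and bending. This note records the models,
the parameters that matter, and the numerical choices, in that order.

## Conventions

Angles are in degrees, measured counterclockwise from the +x image axis with y
taken upward (image rows grow downward, so a filament hanging straight down
has tip angle −90°). Times are in seconds, lengths in pixels. The *tip* of the
filament is the distal 25% of its arc length; the *tip angle* is the first
principal direction of the points comprising that segment, sign-oriented from
the segment's proximal end toward the tip endpoint.

## Synthetic experiment generator

The generator stands in for the raw exposure videos, which are not part of
this package. It emulates the experiment's structure, not its chemistry.

**Exposure design.** One session is `n_blocks` (default 5) independent
uniform-random permutations of the six solution ids, concatenated — 30 trials
by default. Each trial has a fixed exposure duration (default 180 s; the real
trials were ended by visual inspection, so a fixed duration is a
reproducibility choice) followed by a 60 s unrecorded recovery.

**Solution table.** The six built-in mixtures are, as volumes of
acetone/ethanol/water: (60,0,0), (0,60,0), (30,30,0), (30,0,30), (0,30,30) and
(20,20,20) mL; compositions enter the models as volume fractions. An all-zero
composition is accepted as an "empty flask" (no vapor drive).

**Bending dynamics.** The tip angle θ is a weighted sum of three first-order
modes x_i with weights w = (0.7, 0.2, 0.1). During exposure to a solution with
fractions (f_a, f_e, f_w), each mode relaxes toward the deflected target

    θ_target(t) = θ_rest(t) − A·(f_a + f_e + f_w)

at rate ν_i·k, where k = k0 + k_a·f_a + k_e·f_e and ν = (1, 0.2, 0.05).
Because k_a > k_e, acetone speeds the response up much more than ethanol,
while the steady-state deflection A (60°) is the same for every real solution
— response *speed*, not amplitude, carries the composition signal. The
amplitude scale (f_a+f_e+f_w) equals 1 for every real mixture and 0 for an
empty flask, so a no-vapor trial provably stays at rest. During the 60 s
recovery all modes relax toward θ_rest at `k_recover`. A hidden state h
integrates water exposure, dh/dt = (f_w − h)/τ_h during exposure and
dh/dt = −h/τ_h during recovery, and shifts the rest angle: θ_rest(t) = θ_rest0
+ γ_h·h. This is the minimal structure producing slow, water-driven baseline
drift (hysteresis) on top of composition-dependent response speed. I.i.d.
Gaussian noise (σ_θ, default 1°) is added to recorded samples only. All
updates use exact per-step exponential decay factors, so integration error is
nil for piecewise-constant targets.

Defaults: θ_rest0 = −90°, A = 60°, k0 = 0.005, k_a = 0.15, k_e = 0.03 s⁻¹,
k_recover = 0.05 s⁻¹, τ_h = 600 s, γ_h = 25°. The recovery rate makes the
60 s interlude about three recovery time constants — a *substantial but
incomplete* recovery, which matches how the interlude length was chosen in
the experiment. The drift gain makes the water state the dominant source of
initial-angle variation (range ≈ 7–9° per session against 1° sample noise);
with a weaker gain, the residual trial-to-trial carry-over — which is
*anti*-correlated between adjacent trials because permutation blocks sample
solutions without replacement — would mask the positive serial correlation
that the slow state is there to produce. With γ_h ≠ 0 the rest angle moves
during a long exposure, so θ is only approximately monotone within a trial;
with γ_h = 0 it is exactly monotone, and the deflection never exceeds
A + |γ_h| in magnitude.

**Rendering.** Each recorded sample is rasterized as a constant-curvature arc
of fixed arc length (200 px), clamped plumb at a fixed root at the top of the
canvas, drawn as a 5 px stroke of black on white. The arc's curvature is
chosen so that the chord of its distal quarter — the ground-truth tip angle —
equals the sample's angle; for a circular arc that chord direction is the
tangent at 87.5% of arc length, which gives a closed form for the total turn.
The true midline polyline accompanies every frame as ground truth. Geometry
that would leave the canvas raises a render error naming the frame.

**Manual annotations.** Emulated clicks sample 7 points equally spaced in arc
length along the true midline of one frame every 5 s, with isotropic Gaussian
click noise (default SD 2 px).

What the generator does *not* emulate: photorealistic appearance, illumination
and background clutter, out-of-plane twisting, flask headspace chemistry, and
operator-dependent trial durations. Tests passing on this stand-in therefore
validate the *algorithms* (tracking geometry, fit identifiability, model
plumbing), not performance on real video.

## Row-scan tracker

Frames are thresholded (Otsu on luminance by default; fixed threshold
configurable; boolean input is taken as already binary). For every pixel row
the tracker computes the mean foreground column as the midline candidate; rows
with two or more separated foreground runs are split by an exact 1-D two-means
(prefix-sum scan over the sorted columns, the converged k-means solution), and
the two centroids are accepted as a double crossing when both clusters have at
least `max(3, thickness/2)` pixels and are at least 1.5 filament thicknesses
apart, where thickness is the median run length over single-crossing rows.
Candidates are ordered into a single root→tip path by walking down from the
topmost row choosing the nearest continuation, then appending the leftover
(up-going) branch bottom-to-top — this follows a filament that curls back up.
A jump exceeding `max_gap_factor` (default 6) thicknesses truncates the path
and flags it broken; the default is sized to pass the legitimate multi-
thickness midpoint jumps near a horizontal bend (set by bend radius, not
stroke width) while still catching binarization dropouts an order of magnitude
larger.

Three numerical refinements matter in practice:

1. *Midpoint smoothing.* Per-row means carry sub-pixel quantization jitter
   that inflates polyline arc length by several percent; a 5-sample moving
   average along the path removes it (the root point is kept exact).
2. *Tip extension.* Where the filament runs nearly parallel to the scan rows,
   the last row mean sits up to half a run short of the true tip; the path end
   is extended to the farthest stroke pixel along the local tangent.
3. *Pixel-based tip PCA.* The tip angle is the first principal direction of
   all foreground pixels belonging to the tip segment (pixels nearer to the
   distal quarter of the path than to the rest), oriented by the proximal→tip
   chord. Row midpoints sample a near-horizontal tip sparsely and biased;
   the pixel set does not.

With these, noiseless rendered arcs sweeping tip angles −170°…−10° track
within 0.7° and 2.4% of arc length (requirements: 2°, 5%). Frames that fail
(blank, too few rows, degenerate tip) become flagged NaN gaps, never
interpolations. Consecutive angles are unwrapped to the nearest branch
(|Δθ| ≤ 180°).

Manual-annotation comparison rebuilds each annotated frame's midline by cubic
spline through the clicked points (chordal parameterization), measures its tip
angle with the same operation, fits a cubic polynomial predicting automatic
from manual angles, and reports the squared Pearson correlation.

## Shape-ensemble PCA

Each tracked midline is resampled to P = 100 points equally spaced in arc
length (paper-level analyses pool all frames of all trials of one specimen)
and stacked as 2P-vectors (x coordinates then y). PCA is mean-centered with no
per-coordinate standardization (all coordinates share pixel units) and no
Procrustes alignment — overall orientation is the measurement, not a nuisance.
Broken paths shorter than half the nominal filament length are excluded.
Explained-variance fractions come from the full eigenvalue spectrum, so they
sum to 1. On default synthetic sessions the ensemble is effectively a
one-parameter family of arcs, and two components explain ≳99% of variance;
the leading modes act on orientation, as the reconstruction test verifies.

## Transient fits

Each trial's tip-angle transient is summarized by

    θ(t) = a0 + a1·e^(−λ1 t) + a2·e^(−λ2 t) + a3·e^(−λ3 t),

fit by separable nonlinear least squares: the three rates are optimized (log
parameterization, bounds [0.01/T, 300/T] for trial length T) while the four
amplitudes are solved linearly at every step. Starting rate triples are the
deterministic log-spaced triple over [1/T, 30/T] plus seeded log-uniform
triples (10 starts by default). Rates are reported sorted ascending; the SSE
never exceeds the best constant fit because the constant is always in the
model span.

Multi-exponential likelihoods are notoriously degenerate: on slow trials the
SSE surface has plateaus on which rate triples differing by factors of
several are statistically indistinguishable, making the unpenalized arg-min
an essentially arbitrary function of the noise. The fit therefore adds a
small quadratic penalty (weight 0.05·std(θ)) on the log-rates' deviation from
the deterministic anchor. This makes the estimator unique and a smooth
function of the data — which is what the downstream regressions need, since
they consume the parameters as features, not as physical constants — at a
bias that is negligible when the components are genuinely identifiable
(median rate error ≤ 0.4% on noiseless well-separated triples; ≤ 10% at 1°
noise, against a 15% budget).

The *time to maximum deflection* is the first time the deflection |θ(t)−θ(0)|
reaches 95% of its trial maximum, computed on a 1 s moving-median-smoothed
series with linear interpolation at the crossing; trials whose maximum
deflection stays below 3 estimated noise SDs are flagged undefined. For a pure
exponential approach this returns ln(20)/k. The *Δ tip angle* is end minus
start by default (an extremum variant is available).

## Calibration models

R² throughout is the squared Pearson correlation between predicted and actual
values (so a perfectly anti-correlated predictor also scores 1), and all fits
are in-sample ordinary least squares — exploratory calibration summaries, not
held-out performance claims.

*Forward*: Δ tip angle on (f_acetone, f_ethanol, initial angle), with a switch
to drop the initial angle. *Inverse*: one regression per analyte from the
transient parameters, with a feature ablation comparing the full set
(a0..a3, λ1..λ3) against the reduced set (a0, λ1..λ3). Rank-deficient designs
raise a collinearity error naming the offending features; fewer converged fits
than features + 2 raise an under-determined error.

The *hysteresis diagnostic* takes the per-trial initial angles in temporal
order (≥ 10 trials) and reports the linear drift slope (°/trial) and the lag-1
autocorrelation (flagged undefined for constant series). On history-free
sessions the slope is ≈ 0; on default sessions the slow water state makes the
lag-1 autocorrelation positive.

On real films, inverse models of this form were reported to reach roughly
R² ≈ 0.45 for acetone and ≈ 0.30 for ethanol, and the forward model ≈ 0.40;
those values are carried in the pipeline summary for context only. The
synthetic stand-in is cleaner than real video in every respect (known noise,
no twisting, exact model family), so its much higher R² values validate the
pipeline's correctness, not real-world sensing performance.

## Problem sizes and orchestration

The full pipeline (`run_session`, CLI `filmbend run`) chains design →
simulation → rendering → tracking → per-trial splitting → transient fits →
shape PCA → calibration → hysteresis diagnostic; video mode starts at
tracking from frame directories (one directory per trial, since the recovery
interludes were not recorded). Full-scale analyses here use 30-trial sessions
with 180 s exposures sampled and rendered at 5 Hz (27 000 frames per session)
— bending time constants are tens of seconds, so 5 Hz oversamples the
dynamics while keeping a full session's render-and-track pass to a few
minutes; the 30 Hz capture rate remains the generator default for
frame-accurate uses. Outputs are CSV tables with `#` header comments
(package version, seed, config hash) and JSON reports; identical seeds give
byte-identical numeric outputs. All randomness flows from one master seed via
`numpy` seed sequences.

## Known limitations

- The renderer's constant-curvature family cannot represent S-shaped bends;
  the tracker handles them, but the synthetic validation never exercises them.
- Row-scan midlines degrade as any filament section approaches horizontal;
  the pixel-based tip PCA compensates at the tip only.
- The triple-exponential rate ridge trades a small bias for stability; rates
  from trials much shorter than the slowest time constant should be read as
  regression features, not physical constants (the condition number is
  reported alongside each fit).
- Inverse models cannot separate analytes whose only effect is a shared rate
  scale; ethanol recovery relies partly on amplitude/baseline structure and is
  systematically weaker than acetone recovery, by construction.
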