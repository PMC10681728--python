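# Methods

## Scope and models

`curtainkit` quantifies single-molecule DNA-curtain imaging of the Rdh54
translocase and the plate-count genetics used alongside it. Every analysis
stage has a synthetic counterpart in `curtainkit.simgen` with explicit seeds
and per-object ground truth, so the package's claims about its estimators
are made by parameter-recovery experiments rather than by assertion.

### Imaging geometry

Two acquisition modes are modeled (`ImagingConfig`): shuttered two-color
imaging (0.2 s integration + 0.2 s shutter delay → 0.4 s effective frame
interval) and unshuttered photobleaching imaging (0.2 s/frame). Positions
are pixels along the DNA axis with 1000 bp/pixel, the conversion used in
the velocity formula. Defaults are configurable; all are strictly positive
or construction fails.

### Photobleaching and cluster stoichiometry

A focus containing `n` fluorophores is modeled as
`I_t = B + Σ_i a_i·1[t < τ_i] + ε_t` with amplitudes `a_i ~ N(u, s_u)`,
bleach times `τ_i ~ Exp(λ)` i.i.d., and Gaussian camera noise
`ε_t ~ N(0, σ)`. This is additive and spatially uniform by design; EMCCD
excess noise, blinking and local background structure are not modeled.

Step detection fits a piecewise-constant signal by penalized least squares:
minimize `RSS + β·k` over placements of `k` change points with segments of
at least `min_dwell` (default 2) frames. The optimum is found exactly with
PELT; because the squared-error cost is subadditive, pruning preserves
global optimality, and the test suite checks the output set-equal to
exhaustive enumeration of all placements (up to 5 change points) on ~260
seeded traces. The default penalty is Schwarz-style, `β = 3·σ̂²·log T`.
σ̂ is the robust first-difference estimator
`median|ΔI| / (√2·Φ⁻¹(3/4))`, insensitive to the (sparse) true steps.
Boundaries whose level change is below `min_amplitude` (default `2σ̂`) are
merged away, weakest first. Rises (arrivals/blinking) are reported but
excluded from calibration; only drops feed the unit-intensity fit.

The single-fluorophore unit intensity is the Gaussian MLE (sample mean/SD)
of pooled drop amplitudes. Cluster size is
`max(0, I − background) / unit_mean` with a single global flow-cell
background; estimates are real-valued (rounding is the caller's choice) and
exactly equal to the true copy number on noiseless input, which is tested.
Traces with few steps (directly countable; the cohort analyses here use the
detected count itself) validate the calibration; large clusters are sized by
division. The cluster-size distribution family is not identifiable from a
reported median and range alone, so the generator's default is a log-normal
parameterized by median and shape (positive, right-skewed, two parameters) —
a declared choice, with `fixed` and `empirical` alternatives available.

### Translocation kinematics

Each simulated track draws one velocity from a normal truncated at zero.
The truncated distribution is parameterized so that its **mean** equals the
requested mean velocity (the location is solved by root finding); naive
truncation would inflate the mean by ~6 bp/s at the wild-type regime and
make "mean recovery" tests meaningless. Per frame a particle first faces a
termination draw (so `terminate_prob=1` gives a stationary path), then
advances `v·Δt/bp_per_pixel` pixels, and may enter a 2–4-frame pause.
Frame-level jitter enters only through the rendering PSF and noise, matching
per-molecule velocity scatter plots in which each track has one velocity.

Rendering places a Gaussian line profile (SD 1.2 px by default) at each
live particle position over a uniform background; stack mode renders 2-D
frames and returns the kymograph extracted along the center row, so the
render → extract round trip is consistent by construction. Tracking is a
windowed, background-subtracted intensity centroid (sub-pixel), seeded at a
start hint and terminated on signal loss (window max within 2 noise SD of
background).

Motion classification follows the standard scoring rules: translocation
starts when cumulative displacement exceeds 2 px; maximal static runs
(per-frame |Δy| ≤ `static_eps`) of 2–4 frames inside translocation are
pauses; a static run longer than 10 frames terminates the track; runs of
5–10 frames fall between the two definitions and are labeled `stall`
without ending the track. `static_eps` defaults to 1e-3 px/frame: at
0.4 s/frame and 1000 bp/px even a 10 bp/s particle advances 0.004 px/frame,
while a truly stalled particle tracked without noise repeats its centroid
exactly, so the threshold must sit below the slowest real per-frame step —
a much smaller value than one would pick for noisy tracking, where
per-frame stall calls are unreliable regardless.

Velocity is net: `|Y_f − Y_i| · bp_per_pixel / (X_f − X_i)` with the start
taken at the frame where displacement first exceeds 2 px and the end at the
last frame the particle moved (the frame before the terminal stall begins);
paused time counts toward elapsed time. The widely quoted form of this
formula multiplies by a frame rate while quoting times in seconds, which is
dimensionally inconsistent; the implementation uses the
displacement-over-elapsed-time reading, identical when times are counted in
frames. Track length is `|Y_f − Y_i| · bp_per_pixel / 1000` kb, so
`velocity × elapsed = length × 1000` holds identically per track. Tracks
that never cross the start threshold raise an undefined-kinematics signal
and are excluded from statistics rather than scored as zero.

**Selection-aware regime calibration.** The published wild-type numbers
(81.7 ± 51 bp/s; 12.1 ± 7.1 kb) are means over *observed* tracks — those
that crossed the 2-px start threshold before terminating — and the length
is measured from the crossing point. `simgen.calibrate_track_regime` maps
those observed means onto generator parameters analytically: with per-frame
termination probability `p` the number of moving frames is geometric, hence
memoryless, so a track of velocity `v` has expected measured length
`v·Δt/p` regardless of where the crossing fell. This fixes
`p = mean_velocity·Δt / mean_length` exactly, and the generator's requested
mean velocity is then solved so that the selection-weighted mean (weights
`(1−p)^{n_c(v)}`, the probability of surviving to the crossing frame
`n_c(v)`) equals the target. Without this correction the start-rule
selection inflates the observed mean length by ~2 kb and recovery tests
would measure the selection artifact instead of the estimator. A
simulation test validates the calibration at large n.

The generator does not clip tracks at a ~50 kb tether boundary (the
kymograph is as wide as the camera chip, 512 px by default) and does not
model flow or stretching dynamics of the tethered DNA; end effects on the
longest tracks are therefore absent from the synthetic ensembles.

### Colocalization

Foci are matched one-to-one by greedy nearest-neighbor pairing in
increasing distance order (deterministic; ties broken by index), capped at
a capture radius. No radius is standard for curtain data; the default is
1 px (≈ one diffraction-limited focus, ≈1 kb at curtain scale) and is
configurable. On sparse fields greedy matching attains the optimal
assignment size; the tests check it against a Hungarian-algorithm oracle on
random 8-point fields, and matched counts are symmetric under channel swap.
The colocalization fraction is matched-A over total-A and is reported with
its counts (n/N). Occupancy statistics aggregate per replicate field (mean
± sample SD across fields), mirroring error bars computed across
independent experiments, while pooled n/N serves single-cohort fractions.
Intensity correlation is plain Pearson r over matched pairs (≥ 3 pairs,
nonzero variance in both channels). Pixel-wise (Manders-type) image
colocalization is out of scope.

### Genetic-outcome arithmetic

Conversion frequency per replicate is
`selective / (nonselective · dilution · V_sel/V_nonsel)` — the "adjusted"
count scales the non-selective plate back to the same volume of undiluted
culture as the selective plate; the formula is recorded in the result
metadata since conventions vary. Sectored-colony outcomes report
`100·count/total` per replicate with CO+NCO+BIR as the denominator;
"other" categories (chromosome loss, marker-check failures) are accepted in
input but excluded, as the denominator is defined over sectored colonies
only. Survival is `100 · treated/untreated` CFU after dilution adjustment.
The synthetic counterpart draws Poisson counts at the configured event
frequency and plating depth.

Mann–Whitney uses exact full enumeration of assignments for combined
n ≤ 12 (two-sided p = 2·min tail, capped at 1, midranks for ties) and the
tie- and continuity-corrected normal approximation otherwise; the exact
branch is verified against an independent brute-force permutation oracle.
The t test is Welch's (unequal variances) — the variant is a choice, as
reports rarely specify one — with the degenerate both-constant case defined
as p = 1 when means agree. Both tests hold their size: under a true null
(n = 30 + 30, 10⁴ replicates) the empirical type-I error at α = 0.05 is
within 0.05 ± 0.01 in the suite.

## Recovery experiments and problem sizes

`tests/test_acceptance.py` and `scripts/acceptance.py` run the same
experiments; the script reports the recovered values, the tests assert
tolerances stated in sampling-error terms (2 SE for ensemble means, 3
binomial SE for fractions, 3 SE on the Fisher z scale for correlations,
±10% for the cluster median):

* **Tracks**: 400 simulated wild-type tracks (~290 observed after the
  start-rule selection), each rendered into a noiseless kymograph and fully
  re-measured. 400 keeps the ensemble SE of the mean track length (~0.7 kb)
  comfortably below the tolerance while the whole ensemble runs in a few
  seconds.
* **Step counts**: 1000 traces at the published mixture (7% / 59% / 7% /
  26% for 1–4 fluorophores), SNR 5, bleach rate 0.025 s⁻¹ over 1200 frames.
  The rate/duration pair keeps near-simultaneous double bleaches and
  end-of-trace survivors rare (each ~1–3%), the irreducible confusions of
  step counting.
* **Cluster sizing**: unit intensity calibrated from ~440 detected drops in
  150 traces of 2–4 fluorophores, then a 201-focus log-normal field (median
  7.06, shape 0.6) sized end to end.
* **Two-color**: 142 points at 93% matching with 0.3 px registration
  jitter, scored at a 1 px radius; 200 fully matched pairs at ρ = 0.2 for
  the correlation. At n = 200 the sampling SD of Pearson r is ≈ 0.07, so
  recovered values legitimately scatter on that scale; tolerances are on
  the Fisher z scale accordingly.
* **Survival**: 10 replicate treated/untreated platings at 41.6% true
  survival and ~200 CFU per untreated plate.

Passing these suites shows the estimators recover known truth under the
generator's assumptions (Gaussian noise, uniform background, constant
per-track velocity, Poisson plating). It does not certify performance on
real movies with drift, uneven illumination, crossing particles, or
non-Poisson plating variability — none of which the generator emulates.

## Numerical choices and degenerate inputs

* Penalized-fit penalty floor of 1e-9 on exactly noiseless traces, so real
  level changes are still found when σ̂ = 0 while constant traces return no
  steps.
* Cluster-size estimates clamp at zero; size estimation rejects a
  non-positive unit intensity at calibration construction.
* Velocity/track length raise `UndefinedKinematicsError` (never return 0)
  for tracks without a translocation start or with no elapsed time.
* Greedy matching sorts candidate pairs by (distance, index) for
  deterministic output; empty channel A is an error since the fraction's
  denominator would vanish.
* Every generator takes an explicit integer seed (`numpy.random.default_rng`;
  no global state); identical seeds give bit-identical outputs, and
  workflows derive per-object child seeds from a single master seed.
* Zero-variance inputs: correlation and the exact/asymptotic rank test
  reject or saturate (p = 1) rather than emitting NaN.

## Known limitations

* Pause detection operates per frame and is only meaningful when position
  noise is below the per-frame step; for noisy kymographs the pause/stall
  labels should be treated as advisory.
* No multi-particle crossing resolution, gap closing, drift correction, or
  DNA-end registration; one particle per tracking window is assumed.
* The photobleaching model has no blinking (a hidden-Markov treatment is
  out of scope); rises are detected but uninterpreted.
* Colony-count simulation is Poisson-only; overdispersion between
  biological replicates (visible in real assays) is not modeled, so
  replicate SDs from synthetic data understate real ones.
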