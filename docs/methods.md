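# Methods

`optoguide` re-implements, as a reusable and fully tested pipeline, the
quantification and analysis computations used in closed-loop optogenetic
cell-guidance experiments: neutrophil-like cells migrating under agarose are
imaged by TIRF microscopy while a controller places blue-light stimuli at
chosen angles on the cell edge, and the resulting biosensor signals and
trajectories are quantified. Because the pipeline's correctness cannot be
asserted on real microscopy data without re-acquiring it, every stage is
exercised against a synthetic microscope that plants known ground truth.

## Image preparation

Frames are segmented from the PIP₃-biosensor (PHAkt) channel by Otsu
thresholding of a lightly blurred frame (σ = 2 px), keeping the largest
connected component, filling holes, and applying a minimum-area gate
(default 200 px). The thresholding recipe is a design choice — chosen
because it is parameter-free and deterministic — and is not claimed to
match any particular acquisition software.

Illumination background is modelled per channel as either a plane
`z = a·x + b·y + c` (cropped fields) or a full two-dimensional quadratic
`z = a·x² + b·y² + c·x·y + d·x + e·y + f` (full-size frames), fit by
ordinary least squares to pixels outside every cell mask dilated by a
10-px guard band, and subtracted per pixel. The two families reuse the
letters a–c with different meanings; the mapping between them is by
monomial (the plane's a, b, c correspond to the quadratic's d, e, f).
Cells whose background-subtracted pre-stimulus mean is below 100 intensity
units (strict less-than; configurable up to 200) are excluded, since
baseline normalization divides by that number.

Pixel coordinates are 0-based with origin top-left; all angles use the
mathematical convention (counterclockwise positive, 0 along +x), obtained
by flipping the pixel y axis. The default pixel size is 3.0/14 ≈ 0.2143
µm/px, so the standard 14-px mask contraction corresponds to a 3.0-µm
peripheral ring and the 20-px whole-cell sampling square to 4.3 µm.

## Peripheral quantification

The ring mask is the cell mask minus its erosion by a 14-px disk; eroding
a mask to emptiness (a cell thinner than the ring width) raises a
distinct error rather than silently returning the whole mask. Ring-pixel
intensities are binned by angle to the centroid, minus a reference angle —
the direction of net displacement over the first 60 s of the track — into
72 uniform 5° bins by default. The bin count is a design choice (the
underlying method does not pin it); empty bins, which concave masks can
produce, are marked missing and excluded from averages rather than
zero-filled. Binned profiles conserve the ring's total intensity exactly:
the occupancy-weighted bin mean equals the plain ring mean to 1e−9.

Per-frame profiles stack into a time × angle kymograph. Cohort averages
are unweighted means per (time, bin); cells on different time grids are
linearly interpolated onto the first cell's grid with no extrapolation.
For assays where left- and right-turning cells would cancel, single-cell
kymographs are reflected (bin +θ ↔ −θ) when the cell's final x position is
negative in the frame whose +y axis is the initial heading, putting every
cell's "winning side" at positive angles. Fold-change profiles divide the
post-stimulus window mean (default 60 s) by the pre-stimulus window mean
per bin; bins with non-positive pre-stimulus mean are flagged undefined,
never infinite.

## Trajectory kinematics

Trajectories are smoothed in x and y with a Savitzky–Golay filter
(window 9, order 3). Endpoints use scipy's `mode="interp"` — a same-order
polynomial fit over the terminal window — so the filter reproduces cubic
trajectories exactly everywhere; endpoint conventions differ across
implementations, hence this is stated explicitly. The filter's white-noise
SD gain is √(Σc²) ≈ 0.505, i.e. a 1.98× noise reduction; tests assert
against that closed form.

Per-step headings are the angles of consecutive displacements. Steps
slower than 2 µm/min are unreliable and inherit the last confidently
measured heading; steps before the first confident one are flagged
undefined and excluded from alignment logic. The gated series is unwrapped
into a cumulative angle by ±2π corrections.

Outcome logic on top of the heading series:

* **Two-spot classification** — the net displacement is projected onto the
  two stimulus directions; a projection ≥ 20 µm (default) labels the cell
  frontward/rearward, neither labels it a nonresponder, and when both
  exceed the threshold the larger projection wins (the underlying method
  does not define the overlap case). Raising the threshold can never turn
  a nonresponder into a responder.
* **Reversal detection** — a cell is a reverser iff, within a single
  continuous stimulation epoch, its heading comes within 0.4 rad of one
  stimulus angle and, at another time, within 0.4 rad of the other.
  Alignment uses the wrapped angular distance, so a cell that turns a full
  circle is still recognized.
* **Angular velocity** — least-squares slope of the unwrapped angle versus
  time, converted to revolutions per minute (counterclockwise positive).
  The standard phase windows are: full 1-min pre-stimulus window; the
  2 min immediately preceding a local→global switch; the 2 min immediately
  following it.

## Region dynamics

Left/right halves split the mask either at the centroid's x position
(pixels on the divide go left) or across the axis of motion; for a cell
heading straight up the two coincide. The polarity metric is left minus
right baseline-normalized intensity. Whole-cell dynamics are sampled in a
20 × 20-px square centered on the blurred-frame (σ = 5 px) intensity peak,
linked frame-to-frame by nearest-peak matching with a 2-frame gap
tolerance; traces are normalized to the pre-stimulus baseline (≥ 30 s
required) and are invariant to any positive gain applied to the movie.
Initial response rates are least-squares slopes of the normalized trace
over the first 30 s after stimulation.

## Saturable kinetics

Step responses of baseline-normalized traces are fit with the delayed
saturable rise f(t) = 1 for t < τ, s − (s−1)·e^{b(t−τ)} for t ≥ τ, with
s ≥ 1, b < 0, and half-time t½ = −ln 2 / b. Sequential local/global phases
use the two-stage version, continuous at the second knot by construction
through v = s₁ − (s₁−1)·e^{b₁(τ₂−τ₁)}; the middle piece applies for
τ₁ ≤ t ≤ τ₂. Fits use `scipy.optimize.curve_fit` with bounds; τ₂ is
parameterized as τ₁ + Δ (Δ > 0) to keep the knots ordered.
Initialization: s from the trace maximum, τ from the first excursion above
10% of the rise, b from the time to half-rise. Flat traces are flagged
non-identifiable instead of fitted.

Pulse-pair recovery experiments (ratio of second to first peak height as a
function of recovery time) are summarized by fitting
ratio(t) = 1 − (1−r₀)·e^{−kt} and reporting ln 2 / k. The exponential-
approach form is this package's choice of summary model; curves already at
full recovery everywhere are flagged saturated rather than assigned an
arbitrarily small half-time.

## Assay statistics

* Permutation test on |mean(A) − mean(B)| with the cell as the
  exchangeable unit. When the number of distinct group splits is ≤ 10⁵ the
  null is enumerated exhaustively (p is then exact and includes the
  observed labelling); otherwise labels are permuted `n_perm` times with
  the add-one convention p = (1 + #{≥ obs}) / (1 + n_perm), so p is never
  0. Under a simulated null the p-values are uniform (KS < 0.05) and the
  type-I error at α = 0.05 is calibrated.
* Two-proportion Z-test with pooled variance (statsmodels), two-sided;
  pooled proportions of exactly 0 or 1 are degenerate and report p = 1.
* Exact binomial symmetry test against p₀ = ½ (scipy's minimum-likelihood
  two-sided rule), for counts of frontward versus rearward responders.
* One-sample two-sided t test (scipy) for mean angular velocities.

## Stimulus geometry

Candidate objects qualify for an assay when size, intensity and 30-s
motility speed fall within configured gates (defaults: 200–5000 px,
≥ 50 units, 3–30 µm/min; these are configuration, not measured values).
Spots are centered on the boundary point of the current mask at the
requested bearing from the centroid — in the lab frame, relative to the
heading at stimulation onset, or riding the instantaneous heading — with
default radius 5 µm; global patterns dilate the footprint by a small
margin. Placement is equivariant under rotation and is recomputed at every
control step (default 1 s). Protocol phases are half-open intervals
[start, end), so a time exactly on a boundary belongs to the next phase.

## Synthetic microscope

The generator is first-class, tested code; its defaults define the study
conditions used throughout the tests and the acceptance script.

* **Trajectories** — constant-speed motion (default 10 µm/min, cell radius
  8 µm) along mode-specific heading profiles: persistent, fixed-rpm
  turning, u-turn (π rotation over 60 s), reversing (180° switch at a
  planted time), stationary. Gaussian positional noise optional; step
  directions are sampled at mid-steps so a turner's chord directions
  advance at exactly the planted rate.
* **Movies** — a bright disk (peak 500 units) over a planted plane or
  quadratic background with optional Gaussian read noise; peripheral
  intensity optionally polarized toward the heading with a von Mises-shaped
  modulation, never below half peak so segmentation stays trivial at the
  planted contrast. Ground truth (masks, centroids, background grid and
  model, heading series) is returned alongside. Default frame interval
  5 s — an explicit configuration choice, as is everything else here.
* **Adaptive response circuit** — an invented activity-dependent
  negative-feedback ODE, dR/dt = g_a·P − k_d·φ·I·R, dI/dt = g_f·R − k_d·I,
  integrated with fixed-step RK4 at the input sampling interval. With
  feedback intact (φ = 1) a step input overshoots and declines
  (peak/plateau ≈ 2.6 at the defaults g_a = 0.5/s, g_f = 0.05/s,
  k_d = 0.01/s, chosen by forward simulation to land the peak-to-plateau
  ratio in the 2–3 range); a 300-s ramp to the same steady input peaks at
  < half the step peak; with φ = 0 the response is monotone. This is
  synthetic ground truth for testing the analysis, not a model of any real
  signaling circuit.
* **Virtual closed-loop assays** — the membrane is discretized into 36
  lab-frame angular sectors whose local input P relaxes toward its
  illumination at 0.02/s; the heading turns toward sectors with increasing
  P, weighted by a body-frame sensitivity that is zero in a ±60° rear
  sector, zero (saturated) in a ±20° front sector, and tapers linearly
  between, plus small seeded heading noise (SD 0.01 rad/√s). The turning
  gain (7 rad per unit integrated drive) was set by forward simulation so
  that the model robustly reproduces the qualitative phenomenology it is
  meant to emulate: winner-take-all side choice under ±90° two-spot
  stimulation, persistence under front+back stimulation, steady
  counterclockwise turning under a left-edge spot, and a turning-direction
  reversal when switching from local to global illumination. All sector
  widths and gains are configurable; the parameterization is invented.

### What the synthetic data does and does not show

Passing tests demonstrate that the quantification operations recover
planted quantities under controlled conditions — exact geometry, additive
Gaussian noise, circular cells, ideal optics. Real TIRF data have
non-Gaussian noise, irregular and deforming cell shapes, photobleaching,
drift, and segmentation ambiguity that the generator deliberately does not
emulate (no PSF or TIRF-optics model, no shape dynamics). Recovery
accuracies measured here are therefore upper bounds on real-data
performance; the qualitative assay contracts test the *logic* of the
pipeline, not the biology.

## Problem sizes

The default test and acceptance runs use desk-scale problems: 100×100 to
200×200-px frames, cohorts of 6–20 synthetic cells, 300–420-s assays at
1-s control and 5-s frame intervals, 1000-replicate null simulations at
199 permutations, and 100-seed Monte-Carlo studies for the recovery
half-time. These sizes were chosen so the full suite characterizes every
stage in a few minutes on one CPU.

## Known limitations

* Single-cell scenes: no multi-cell tracking beyond nearest-centroid/peak
  linking, no contact handling.
* The behavioral model's winner-take-all outcome depends on its invented
  sensitivity profile; it demonstrates the controller/analysis loop, not a
  mechanistic prediction.
* The recovery-half-time functional form is a summary model; reported
  half-times are conditional on it.
* Headline experimental numbers (population reversal fractions, measured
  recovery half-times) require the original microscopy data; the package
  exposes the exact computations (`detect_reversal` over cohorts,
  `recovery_half_time`) that produce them given such data.
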