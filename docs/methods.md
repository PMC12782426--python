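# Methods

This note documents the models, numerical choices, and limitations
behind `erkmech`, in the spirit of a package methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The convolutional acceleration model

Each cell is assumed to set its acceleration along one axis from a
linear functional of its recent inputs:

    a(t) = w0 − w1·x1(t) + Σ_{i=2..5} Σ_{τ=0}^{L−1} w_i(τ)·x_i(t−τ)

The instantaneous form of this law (L = 1) is the continuum limit of a
spring-particle tissue: ERK-dependent friction contributes the velocity
term, ERK-dependent cell size the ERK-gradient term, elasticity the
density-gradient term, and tissue viscosity the velocity-curvature
terms. `coefficient_map` exposes that correspondence
(c_vel = −μ0(1−β·ERK̄), c_erk = −2αkR0/ρ̄, c_rho = −k/ρ̄³,
c_visc = η/ρ̄², valid only at high density ρ̄ > 0). The temporal
extension replaces the constant coefficients with lag kernels
("response functions") so that cells may weight the recent *history* of
each cue, not just its current value.

Modeling conventions:

- **Velocity has no history.** Acceleration is the derivative of
  velocity; a free temporal kernel on x1 could reproduce the target
  nearly exactly and mask every other input. x1 enters only at lag 0.
- **Sign convention.** The solver fits an unconstrained coefficient on
  x1 and reports w1 as its negative, so positive w1 reads as
  friction-like damping.
- **Time step absorbed.** The discrete convolution carries no explicit
  Δt factor; kernels are in per-input-unit per frame². Positions are in
  pixels and times in frames internally; the 2-min frame interval is
  applied only when reporting physical units (a doubled frame interval
  halves velocities and quarters accelerations).
- **Lag window.** L = 20 frames (40 min) by default; in practice fitted
  kernels decay within ~10 frames, so the window is generous.

## 2. Feature extraction

- **Temporal derivatives**: second-order Savitzky–Golay filter, window
  11 frames. At each interior frame the filter equals the analytic
  first/second derivative of the local least-squares quadratic, hence is
  exact on polynomial trajectories up to degree 2. Frames lacking a full
  centered window are dropped (no mirroring): edge extrapolation would
  bias exactly the frames that become regression targets, and each track
  loses only (window−1)/2 frames per end.
- **Spatial derivatives**: full six-term 2D quadratic
  (1, x, y, x², xy, y²) least-squares fit to neighboring cells within a
  radius, centered on the focal cell (focal cell included). Center-
  relative coordinates make the fit translation invariant; derivatives
  are read analytically from the coefficients. Fewer than six in-radius
  points, or a rank-deficient design (e.g. collinear neighbors), flags
  the record unusable — records are dropped with a reason count, never
  imputed. The ERK fit radius is 10 px; the velocity fit radius defaults
  to the same 10 px and the density fit reuses the velocity radius (only
  the ERK radius is pinned by the source analysis; all are
  configurable).
- **Density**: Gaussian KDE with σ = 25 px, the focal cell's own kernel
  included, so the field integrates to the cell count. Density gradients
  come from the same quadratic fit applied to per-cell KDE values
  (cell-centric, no raster), so the whole pipeline needs only the track
  table.
- **Axes**: for the wound-orthogonal axis the features use v_x and
  x-derivatives of ERK/ρ; for the parallel axis the matching component
  v_y and y-derivatives. The velocity-curvature features are always the
  pure second derivatives of the chosen component along x and along y.
  The symmetric reading is the only consistent one when both axes are
  fitted with the same five-feature set.
- **Trajectory filters**: tracks shorter than 400 frames, containing
  missing values (including frame gaps, which are re-indexed to explicit
  missing rows on load), or — optionally — not starting at the dataset's
  first frame are discarded, mirroring standard preparation of wound-
  healing tracking data.
- **Ratio imaging**: FRET and CFP frames are Gaussian-smoothed
  (σ = 1 px) before background subtraction and pixel-wise division;
  nonpositive denominators are masked NaN and counted.

## 3. Ridge fitting and cross-validation

The lagged design matrix has one row per (cell, frame) with L lags of
history inside that cell — rows never span cells — and 2 + 4L columns.
The solver minimizes ‖y − Xθ‖² + λ‖θ_pen‖² by the normal equations with
the bias excluded from the penalty (standard practice; it keeps the
λ→∞ limit interpretable as "predict the mean"). Features are *not*
standardized by default, so reported λ values refer to raw units; a
`standardize` switch z-scores the penalized columns and rescales the
kernels back to raw units after fitting.

λ is selected by k-fold cross-validation (k = 5): a broad geometric grid
10⁻⁴…10⁴, then a refined grid spanning one decade either side of the
broad argmin at 20 points per decade; exact ties go to the larger λ
(more regularization). Folds are sample-wise (shuffled with the seed) by
default, or cell-wise (grouped, so a cell never straddles train and
validation) as a variant; `grouped_cv_stability` refits the model on
leave-cells-out folds and reports the pairwise cosine similarity of the
fold kernels as a stability diagnostic. The per-fold search costs one
Gram matrix per fold; each λ is then a p×p solve.

## 4. Heterogeneity analysis

Per-cell response functions are ridge fits on each cell's own rows at
the population-level λ (per-cell CV is possible but a shared penalty
keeps kernels comparable). Cells are scored by the Pearson correlation
between observed acceleration and the *population* model's prediction
and ranked descending; undefined correlations (constant series) score
NaN and rank last, ties break by cell id. The similarity matrix uses
cosine similarity of flattened kernel vectors in the fixed order
[w1, w2(0..L−1), w3, w4, w5] — the bias is excluded by default (it is
not a response to any input) and the velocity coefficient included;
both are switchable. PCA is applied to mean-centered vectors without
per-feature scaling. Subgroup means average the top-n and bottom-n
cells by rank. Cohort analyses (e.g. wound-front vs interior cells) are
the same code path run on a subset table; cohort selection is the
caller's responsibility.

## 5. The 1D spring-particle epithelium

Cells are particles on a line, each coupled to its neighbors by springs
of natural length R_i + R_{i+1}; end cells have a single neighbor.
Friction is μ_i = μ0·e^(−β·ERK_i); the radius follows either the
instantaneous ERK level, R_i = R0(1 + α·ERK_i), or its time derivative,
R_i = R0(1 + α·∂ERK_i/∂t), the latter implementing the
differentiator-like ERK response learned from data. ∂ERK_i/∂t is taken
analytically as −σ·ERK_i + L_i (exact and step-size independent, never
finite-differenced). ERK follows dERK_i/dt = −σ·ERK_i + L_i with a
binary illumination band of width 30 cells sweeping at 0.1 cells/min in
cell-index space. The optional neighbor-viscosity term
η(v_{i+1} − 2v_i + v_{i−1}) defaults to 0; end cells couple viscously to
their single neighbor, which makes the viscous coupling exactly
momentum-conserving together with the telescoping spring forces.

**Integration.** Fixed steps of dt = 0.01 min: the ERK equation advances
by its exact exponential update (exact for piecewise-constant
illumination), mechanics by semi-implicit Euler (accelerations from the
current state, then positions from the updated velocities). Halving dt
changes final positions of the reference runs by well under 10⁻³
relative. Cell crossings abort with the offending index and time;
non-finite states abort naming the step size. Initial condition: cells
at rest, uniformly spaced at 2R0 (the zero-ERK equilibrium), ERK = 0.

**ERK normalization in the reference wave runs.** The gains of the
reference parameter set (β = 2.5, α = 1.5 instantaneous / α = 10
derivative, with α·σ = 1) are calibrated for ERK activity of order one,
as a FRET-ratio readout is. A lit cell's ERK plateaus at
amplitude/σ, so the reference runs use illumination amplitude σ
(plateau 1). With amplitude 1 instead (plateau 10) friction would
collapse by e^(−25) and radii would swing an order of magnitude past any
physical range, and the derivative-rule chain inevitably develops cell
crossings — numerically verified, which is why the normalized amplitude
is the package default for these runs. The band initially covers cell
indices [60, 90), so it sweeps the mid-chain observation region within
the 7-hour run.

**Wave-response measurement.** For each cell whose illumination onset
falls at least 30 min after the start and 90 min before the end of the
run (excluding 10 boundary cells), the arrival excursion is the largest
transient displacement in the wave direction within [onset − 30 min,
onset + 90 min], relative to the position 30 min before onset — the
transient trough sits ~20–25 min after onset; net displacement is
x(end) − x(0). The instantaneous rule produces a clear co-wave arrival
excursion; the derivative rule suppresses it to below a tenth while
both preserve net counter-wave migration.

## 6. Synthetic ground truth

`generate_linear_response_dataset` draws each feature as a stationary
AR(1) (discrete Ornstein–Uhlenbeck) process, lag-1 autocorrelation 0.9
by default, so the inputs have correlation times comparable to the lag
window — white-noise inputs would make kernel recovery unrealistically
easy. The target is exactly the convolutional model plus Gaussian noise
whose SD is quoted as a fraction (default 10%) of the noiseless target
SD over design-complete frames. Defaults mirror the imaging study's
scale: 300 cells, 400 frames per track, 2-min frames. The reference
ground-truth kernels are a biphasic ERK-gradient kernel (positive peak
at lag 0, undershoot near lag 4, zero within ~10 frames), a slower
negative density hump, and two smooth delayed viscosity humps of
comparable norms, so per-kernel recovery error is meaningful.

What the generator does *not* emulate: measurement noise on the features
themselves (errors-in-variables), segmentation or tracking errors beyond
planted truncations and missing values, cell division, nonlinear or
non-stationary response rules, and feedback from motion onto ERK.
Passing recovery benchmarks therefore demonstrates correctness of the
estimation machinery under the model's own assumptions, not robustness
to every pathology of real imaging data.

`generate_two_population_dataset` plants two rule-subpopulations. With
`flip='erk'` only the ERK kernel changes sign — a deliberately subtle
structure whose ideal similarity contrast is capped near 0.5 because the
other kernels are shared; with `flip='full'` group B follows the fully
inverted rule, planting a strong two-block structure (ideal contrast
≈ 1.9). The block-contrast benchmark uses the full flip; the subtle
variant exercises qualitative block detection.

## 7. Problem sizes and determinism

The acceptance script runs the recovery benchmark at 300 cells × 400
frames (≈ 91k design rows × 82 columns), the heterogeneity benchmark at
60 cells × 400 frames, and both reference wave runs at 42,000 steps ×
100 cells — sizes chosen so the whole script completes in tens of
seconds on one CPU while matching the study-scale trajectory counts and
lengths. All randomness flows from explicit seeds; identical seeds give
bit-identical synthetic tables and model files. The reference wave runs
contain no randomness at all.

## 8. Known limitations

- The regression is linear; threshold, saturating, or cooperative
  responses are out of scope (kernels then capture only the best linear
  approximation).
- The model is deterministic: intrinsic motility noise appears only in
  residuals, not as a modeled stochastic term.
- The continuum coefficient mapping is valid only in the high-density
  regime and is provided for interpretation, not fitted.
- The spring chain is 1D and one-way coupled (light → ERK → mechanics);
  there is no feedback from motion or contact to ERK, so the simulator
  cannot generate ERK wave patterns self-consistently.
- Cell detection and tracking are upstream concerns: the package
  consumes tracker output tables and never attempts to fix identity
  switches or detection gaps beyond discarding affected tracks.
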