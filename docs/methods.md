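# Methods

## Task model

The dimensionless goal function is f(x, v) = v²/μ + x − L̃ with L̃ = L/R = 10
for the default geometry (L = 200 cm target distance, R = 20 cm length
scale, g = 981 cm/s²; speeds are scaled by √(2gR)). f equals the stopping
error in units of R, and its zero set — the GEM — is the parabola
v² = μ(L̃ − x). The frame at an operating point (x*, v*) consists of
A = (1, 2v*/μ), the unit tangent ê_t ∝ (−2v*/μ, 1), the unit normal
ê_n = A/‖A‖, and the passive sensitivity s = ‖A‖ = √(1 + (2v*/μ)²) ≥ 1.
The operating point need not lie exactly on the GEM; A is evaluated at the
given point, which for near-GEM data is equivalent to using the tangent of
the error contour through it.

Friction conditions are generated from ideal-trial stop times: a release
from x = 0 at the speed that stops exactly on the target stops after
t = √(2L/(μg)), so μ = 2L/(gt²). Eight stop times uniformly spaced on
[3, 5] s give μ from ≈ 0.045 down to ≈ 0.016; the four largest times form
the low-friction (high-sensitivity) set. The exact per-condition μ values of
any particular experiment are reconstructed from this rule, not tabulated.

## Fluctuation model and simulator

Inter-trial fluctuations about the operating point follow
u[k+1] = B u[k] + ν[k]. The simulator constructs B from ground-truth
eigenvalues (λ_w, λ_s) and eigenvector angles (θ_w, θ_s) measured from the
GEM tangent: ê_w = cos θ_w ê_t + sin θ_w ê_n (similarly ê_s), and
B = E diag(λ_w, λ_s) E⁻¹ with E = (ê_w | ê_s). Noise is specified as
independent zero-mean Gaussians (σ_nw, σ_ns) in the eigendirections and
mapped through E, so the laboratory-frame noise covariance is
E diag(σ²) Eᵀ (E is generally non-orthogonal). Iteration starts from u = 0
with a 200-iterate burn-in rather than a stationary-distribution draw —
simpler, and exactly reproducible from a seed. Recorded errors use the exact
nonlinear goal function at the release state, so simulated data carry the
same (small) linearization error as real data. Signal-dependent noise is not
simulated: it has no leading-order effect on the linearized inter-trial
dynamics, and including it would require inventing an unmeasured form.

Defaults encode the study conditions: λ_w = 0.76, λ_s = −0.03, θ_w = 1°,
θ_s = 80°, 10 blocks × 50 trials, σ_nw = σ_ns = 10⁻³. The noise covariance
of real participants is unknown; equal eigendirection components are a
neutral choice, and 10⁻³ keeps RMS fluctuations near 0.1% of the state scale
— small enough that the linearization holds to a few percent, while giving a
goal-level RMS error of order 1 cm at s ≈ 50, consistent with skilled
performance (mean error within 10% of the target distance). Optional
measurement noise (fraction 0.02 emulates ~2% apparatus precision) perturbs
only the recorded states. A master seed spawns per-condition seeds through
`numpy.random.SeedSequence`.

What the simulator does **not** emulate: learning transients within or
across blocks, drift of the operating point, signal-dependent noise, heavy
tails or outlier trials, and within-trial movement dynamics. Passing tests
therefore certify the estimation machinery under the model's own
assumptions, not the validity of those assumptions for any particular
dataset.

## Estimation conventions

The operating point is the sample-mean state over the full series, computed
once and held fixed (including across bootstrap iterates). Regression pairs
(u_k, u_{k+1}) are formed within blocks only: the first 4 trials of each
block are dropped (retraining transients) and only the first 49 trials serve
as current states (no spurious cross-block update), leaving 45 pairs per
50-trial block — 450 pairs for a 10-block series. B is the ordinary
least-squares minimizer of the one-step prediction error, closed form
B = (Σ u' uᵀ)(Σ u uᵀ)⁻¹, without intercept (fluctuations are mean-removed by
construction). Measurement-noise attenuation of the OLS estimate is accepted
untreated at the ~2% precision level.

Eigenanalysis requires real, distinct eigenvalues; complex or repeated pairs
raise typed errors. Labeling: *weak* = larger |λ| (ties broken toward the
larger algebraic value), which is well-defined when λ_s < 0; a diagnostic
relabeling by tangent alignment is implicit in the reported angles. Signs
are fixed by ê_w·ê_t ≥ 0 and ê_s·ê_n ≥ 0, making θ_w a signed angle in
(−90°, 90°] and θ_s ∈ [0°, 180°); β = sin θ_s ≥ 0. Residuals in
eigencoordinates, r_k = E⁻¹(u_{k+1} − B u_k), give σ_nw, σ_ns as RMS
components (the RMS reading of the residual second moment).

## Persistence

R(1) is the lag-1 product ratio on mean-removed data with the denominator
over the same current-state sample as the numerator, so for AR(1) data it
coincides with the autoregression OLS slope and equals the eigenvalue in
expectation; lag-1 products never span block boundaries. DFA uses linear
detrending: integrate the mean-removed series, partition into
non-overlapping boxes (tail remainder discarded), remove the per-box
least-squares line, F(n) = pooled RMS residual, α = slope of log₁₀F vs
log₁₀n. Box sizes default to ~12 log-spaced integers in [4, N/4]; the exact
grid is a package choice, pinned by calibration (white noise → α = 0.5,
integrated noise → α = 1.5). DFA runs on the concatenation of all blocks
with the first 4 trials of each removed (460 trials for full-length data).
α is used strictly as an overall persistence measure, not as a long-range
correlation claim.

## Bootstrap

The resampling unit is the (current, next) pair, drawn with replacement at
the full pair count; each iterate refits B and recomputes every quantity.
For DFA, each iterate's eigenvectors re-express the entire concatenated
series before the exponents are computed — resampling feeds the eigenbasis,
never the temporal ordering. Iterates with complex or repeated eigenvalues
are dropped and counted (a diagnostic error fires above 20%); re-drawing
would couple iterates. Intervals are plain 2.5/97.5 percentiles; the default
is 10000 iterates with a `--fast` mode (2000) for CI-insensitive checks.
Aggregation across conditions pools raw samples, which reproduces wide
aggregate intervals where conditions disagree (e.g. θ_s). The per-iterate
arithmetic (OLS solve, 2×2 eigenanalysis, angles, residuals) is evaluated in
closed form across the whole iterate batch, in chunks of 2000 to bound
memory.

For the scaling bootstrap, each iterate resamples every condition's pairs
and recomputes σ_e (std of goal error over the resampled current trials),
σ_ns, s (from the resampled mean release speed), β and λ_s, then fits
(a, b) across conditions; iterates dropped in any condition are dropped in
all to keep fits aligned. The reported (a, b, R²) come from the single
pooled fit over all iterate-points, which agrees with the per-iterate mean
to well under 1%.

σ_e is the standard deviation of e about its own mean — skilled performers
are treated as unbiased, and the mean error is reported separately as a
skill diagnostic.

## Hypothesis verdicts

H1: CI(λ_w) ⊂ (0, 1), CI(θ_w) intersects ±10°, |mean θ_w| < 10°.
H2: |mean λ_s| < 0.2 and mean θ_s exceeds |mean θ_w| by > 15°.
H3: CI(R_w1) excludes 0, CI(R_s1) contains 0, CI(α_s) contains 0.5, and
mean α_w − mean α_s > 0.2. H4: CI(a) contains 1. The thresholds are package
defaults chosen loose relative to the expected effect sizes (the theory
states orderings, not cutoffs); they are configurable and echoed in the
report next to the raw values.

## Coordinate invariance

A coordinate change u = T v (T the Jacobian at the operating point for
nonlinear maps) turns the fitted matrix into T⁻¹BT — same eigenvalues — and
maps the GEM tangent to the normalized T⁻¹-image; the transformed normal is
taken as the unit A_new = A T direction, which is automatically orthogonal
to the transformed tangent. Only linear transforms are exercised in tests.
The whitening transform uses the principal axes C and principal values d of
the fluctuation covariance, T = C diag(√d), making the new sample covariance
the identity: variance-based GEM detection fails by construction while the
eigenstructure is unchanged. "Same pairs, deterministic transform" checks
agree to 10⁻⁸; under strong shear the *angles* deform in proportion to the
condition number of T, but the weak-tangent/strong-transverse ordering
survives.

## Numerical choices and problem sizes

Eigenvalue reality/degeneracy tolerance 10⁻⁹ (relative); OLS rank guard at
condition number 10¹²; bootstrap chunk size 2000 iterates. The test suite
uses 200 seeds × 8 conditions for recovery/coverage (bootstrap n_iter 1000
for interval coverage, where percentile endpoints are stable to a few
percent of the CI width), 50 seeds for the scaling-fit coverage (n_iter
1000), and 10⁵-sample series for the autocorrelation identity; the
acceptance script runs the full pipeline at the study's 10000 iterates.
These sizes are the package's reproducibility conditions and are stated in
the relevant docstrings.

## Known limitations

- Real, distinct eigenvalues are assumed throughout; oscillatory inter-trial
  dynamics (complex pairs) are rejected, not analyzed.
- OLS is biased toward zero under heavy measurement noise
  (errors-in-variables); no total-least-squares variant is provided.
- The pooled-sample aggregation is one of several defensible ways to combine
  conditions; it weights conditions equally by iterate count.
- The simulated R² of the scaling fit (~0.92) is below the value a tight
  experimental dataset can reach, since the per-condition bootstrap scatter
  here is driven entirely by estimation noise at N = 450, and the simulated
  s_TOT values span a narrower range than an experiment with more extreme
  friction contrasts would give.
- DFA on 460 trials is adequate for separating α ≈ 0.5 from α ≈ 1, not for
  precision estimates of long-range exponents.
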