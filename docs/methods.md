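# Methods

This note documents the models, estimators, numerical choices and synthetic
data underlying `dynstab`, and what the package's tests do and do not show
about real recordings.

## Windowed linear model and estimator

Each window of w samples is modelled as x(k) = A x(k−1) + ε(k) with no
intercept (recordings are assumed high-passed, so channel means are ≈ 0; a
zero-phase 4th-order Butterworth high-pass with 0.1 Hz default cutoff is
provided, chosen because forward–backward filtering leaves event times
aligned and the passband gain is within 1% at physiological frequencies).
Windows are half-open sample intervals [start, start + round(window_s·fs)),
advanced by round(shift_s·fs) samples, reported at their center time. The
defaults — 1 s windows, 100 ms shifts — balance stationarity within a window
against enough samples (512 at 512 Hz) to estimate an n×n matrix for n of
order tens.

A is the ordinary least-squares minimizer of Σ‖x(k) − A x(k−1)‖², computed
via the Moore–Penrose pseudoinverse of the lagged regressor block, so
rank-deficient windows still return the minimum-norm solution. A window is
flagged `degenerate` when the regressor rank is below the channel count: the
fit is reported but the dynamics are not uniquely identified there, and such
windows are excluded from feedback design. An optional ridge parameter
(default 0, i.e. plain least squares) is exposed for ill-conditioned data.

Model-order diagnostics fit VAR(p) for p = 1..p_max by least squares (each
order on its own w − p targets) and report
AIC(p) = ln det Σ̂_p + 2pn²/T_eff and BIC(p) = ln det Σ̂_p + pn² ln(T_eff)/T_eff.
Singular residual covariances fall back to the log pseudo-determinant and are
flagged. These diagnostics are informational: all eigenmode analytics operate
on the first-order fit, where the eigenvalue–frequency correspondence is
direct.

## Eigenmodes

The decomposition uses the general similarity A = V Λ V⁻¹ (fitted matrices
are generically non-symmetric, so an orthogonal eigendecomposition would be
wrong). Mode trajectories z_i(k) use left eigenvectors (rows of V⁻¹), so
z(k) = Λᵏ z(0) holds exactly for noiseless data. Conventions and tolerances:

- Conjugate pairs describe a single oscillation and are retained once
  (θ ≥ 0); unpaired real eigenvalues are marked `is_real_mode`.
- Frequency f = |θ|·fs/2π Hz and growth rate ρ = fs·ln|λ| s⁻¹ interpret the
  sampling interval as the unit time step, which reproduces a planted 64 Hz
  rotation at 512 Hz exactly.
- Eigenvalues with modulus below 1e−9 of the spectral scale are numerical
  nulls (they arise in rank-deficient windows); their angle is meaningless,
  so their frequency is reported as 0 Hz rather than as a spurious Nyquist
  oscillation.
- A window whose eigenvector matrix fails the reconstruction test
  ‖A − VΛV⁻¹‖_F ≤ 1e−8‖A‖_F is treated as defective: the decomposition is
  retried on a tiny seeded perturbation (1e−10 → 1e−6 of ‖A‖) and the window
  is flagged; defective windows are skipped in feedback design.
- Loadings are |v|/max|v| with the peak entry pinned to exactly 1.

Band statistics restrict to modes with frequency in [f_lo, f_hi) — defaults
gamma 25–55 Hz and beta 12–25 Hz, with alpha 8–12 Hz as a conventional,
configurable third band — average the loadings across in-band modes
per channel (a dominant-mode option is exposed; averaging is the default),
and report the maximum and the population (non-excess) Pearson kurtosis
m₄/m₂² of that per-channel profile. Kurtosis of an empty band or a
zero-variance profile is flagged undefined, never thrown. The per-mode
records of the mode table also carry each mode's own loading kurtosis as a
focality index; mode ids rank modes by frequency, descending, within each
window.

The onset contrast is a two-sided Wilcoxon rank-sum test with midranks for
ties: exact by exhaustive enumeration of allocations for combined samples up
to 12, otherwise the tie-corrected normal approximation without continuity
correction (the convention is fixed and cross-checked against an independent
implementation in the tests). Default contrast windows are 5 s before vs 5 s
after the onset event; windows with undefined statistics are dropped.

Mode identity across windows (and between open and closed loop) is by
frequency-descending rank, not eigenvector continuity — a presentation
convention, not a claim about mode correspondence when frequencies cross.

## Feedback design

The design problem — one constant output-feedback gain that damps the fast
modes of a *switching* set of window matrices {A_j} — is split into an exact
and a least-squares sub-problem:

1. **Spectrum reassignment (exact, per window).** Every eigenvalue with
   frequency strictly above `f_thresh` and modulus strictly above `r_target`
   moves to r_target·e^(iθ) (angle preserved; real eigenvalues keep their
   sign; conjugate partners move together, so Ã = Re(V Λ̃ V⁻¹) is real up to
   rounding, with the imaginary residue checked against 1e−8‖A‖).
   Eigenvalues already inside the target radius are left free rather than
   re-pinned: the objective is damping, not pinning. Δ_j = Ã_j − A_j is the
   exactly-stabilizing perturbation.
2. **Projection onto the actuation-realizable set (least squares, across
   windows).** For selection matrices B (stimulating electrodes) and C
   (sensing electrodes), Σ_j‖B K C − Δ_j‖²_F separates entrywise and its
   unique minimizer is the mean of the Δ_j restricted to the actuated block;
   general B, C are handled by K = B⁺ (mean Δ) C⁺. Convexity makes this the
   global optimum, which the tests verify against a derivative-free numeric
   minimizer and by random perturbation.

Defaults: f_thresh = 15 Hz (fast activity above the beta edge), r_target =
0.8 — a damped radius giving a ~4.5 ms e-folding decay at 512 Hz, safely
inside the unit circle but not so aggressive that the projected gain grows
large. Both are configuration values. The closed loop is A + B K C with an
additive sign convention; damping comes from the value of K.

Electrode selection ranks channels by mean in-band loading across a window
range (ties to the lower index) — the model-based analogue of choosing
stimulation sites at the electrodes most involved in the emerging
oscillation. The all-electrode baseline wraps the Kautsky–Nichols
state-feedback placement; a requested spectrum equal to the open-loop one
returns the zero gain, and an unassignable request (uncontrollable mode)
raises.

Closed-loop simulations draw one innovation sequence per run and feed the
identical noise to the open and closed systems, so trajectory differences
are attributable to the gain alone. The simulation deliberately assumes
stimulation does not alter the underlying window matrices; plant–model
mismatch is outside the package's claims. The offline scenario designs one
gain on the first 10 onset windows of each training seizure (4 × 10 = 40
windows by default) and evaluates it on a held-out seizure's onset windows.

## Synthetic data

Two generator families stand in for iEEG, which cannot be distributed:

**Enveloped-sinusoid mixtures.** Sources are sin(a·t + b) under an
exponential envelope e^(c·t) (baseline; c < 0 damps, c > 0 grows) or a
Gaussian-bell envelope (transient), active on [t_on, t_off), mixed linearly
onto channels; consecutive sources lead each other by π/2 by default. The
transient envelope is implemented in the exact non-standard form
(1/(2σ√(2π)))·e^(−(t−μ)²/σ²) — prefactor 2σ√(2π) and no factor 2 in the
exponent — with an optional peak-normalized variant; the form is kept as
specified rather than silently "corrected" to a Gaussian density. Time is in
seconds, so a source's frequency a/2π is sampling-rate independent.

The canonical 4-channel, 512 Hz, 10 s dataset plants: a 5 Hz baseline
damping at c = −0.4 s⁻¹ (present throughout, so no window is empty); a 20 Hz
Gaussian transient around 4.5 s; and a growing (c = +0.5 s⁻¹) 64 Hz pair
active over 6–8 s mixed onto channels 1 and 3 only. Realizing the
high-frequency component as two consecutive sources puts them in phase
quadrature, so the planted oscillation is exactly a 2-D rotation–scaling
process — recoverable by a first-order fit, which a single-phase (spatially
rank-1) sinusoid is not. Only the 64 Hz component is treated as ground
truth; the other frequencies, envelopes and weights are fixed pedagogical
constants, and the dataset is noise-free and fully deterministic.

**Focal switching surrogates.** A 20-channel (default) piecewise-LTI system
switching every 1 s, driven by Gaussian noise (sd 0.05). Pre-onset segments
are random stable backgrounds: radius-0.95 orthogonally-delocalized
rotation-block matrices with frequencies drawn uniformly over 0.5–100 Hz, so
several gamma-band modes with spread-out eigenvectors exist before onset.
From onset (10 s into a 20 s run), every segment embeds a fixed 2×2
rotation block at f_ictal = 30 Hz and radius 1.0 (sustained, neither decaying
nor exploding over the simulated horizon) whose eigenvectors are supported
exactly on the 4 SOZ channels with a tapered involvement profile (loadings
1 → 0.55 across the SOZ, random phase pattern), while the background slows
to 0.5–15 Hz — emulating the classic onset picture of low-voltage fast
activity confined to the SOZ against background slowing. The background is
redrawn each segment (the switching that motivates the generalized design);
the ictal block is held fixed, and an `ictal_seed` separates the ictal
generator from noise/background seeds so stereotyped seizure ensembles can
share one focus. Ground truth (planted eigenvalues, basis, loading profile)
is returned alongside the recording, and the onset is marked as a UEO event.

**What the surrogates do not emulate:** 1/f background spectra, nonlinear
and nonstationary waveform morphology, spatially correlated measurement
noise, volume conduction, artifacts, and plant changes under stimulation.
Passing tests therefore demonstrate correctness of the estimator, the
statistics and the control design under the stated linear-switching
conditions — not clinical performance.

## Problem sizes and determinism

The test suite and the acceptance script run on desk-scale problems: the
4-channel canonical dataset (91 windows), 20-channel/20 s surrogates
(191 windows each), 5-seed replications, and 4+1-seizure train/test
ensembles. All randomness flows through seeded numpy Generators; the
canonical dataset is deterministic by construction, and the pipeline CLI
derives per-stage seeds from a single configuration seed by fixed offsets.

## Known limitations

- Eigenvalue estimates of strongly non-normal window matrices are
  ill-conditioned; recovery guarantees in the tests use well-conditioned
  (orthogonal-family) systems, and real fits should be read with the
  reconstruction and degeneracy flags in hand.
- Rank matching of open/closed (and across-window) modes can mispair when
  frequencies cross; the report exposes raw per-mode records so alternative
  matchings can be applied downstream.
- The least-squares projection offers no guarantee on untargeted modes; the
  evaluation deliberately reports their movement instead of suppressing it,
  and no stability margin of the closed loop is certified beyond what the
  evaluation measures.
- VAR(p > 1) eigen-analysis, Kalman filtering, stimulation-artifact and
  actuator-saturation modelling are out of scope.
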