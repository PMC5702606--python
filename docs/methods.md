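# Methods

## The two-equilibrium activation model

The package models a GPCR observed through methyl-methionine reporters as a
system of two coupled fast-exchange equilibria. For the free receptor,
ligand binding positions the equilibrium between an inactive state (I) and a
pre-active state (A); for the nanobody-bound receptor, between a less active
(A^G−) and a fully active (A^G+) ternary state. With exchange fast on the
NMR timescale, each reporter shows one peak at the population-weighted
shift, so state populations map linearly onto peak positions and ligand
efficacy ε (percent of full-agonist response, 0–100) is an affine function
of the shift pair, ε = a·δ_H + b·δ_C + c.

The synthetic generator takes this model literally: p_active = ε/100 for
ligand-bound and ternary states, p_A = 0.02 for the apo receptor (low basal
activity), and p = 0 for the nanobody-only basal complex, which sits at the
A^G− end of the ternary axis. The per-ligand efficacies
(7-methylcyanopindolol 5, carvedilol 10, cyanopindolol 15, salbutamol 50,
isoprenaline 95, adrenaline 100) are placeholders consistent with the
pharmacological classes and are overridable per state.

### Endpoint shifts

For the reporters with published plane coefficients (M223 and M296 in the
ligand series; M178, M296, M223 and M153 in the ternary series), the default
endpoint shifts are obtained by inverting the plane: an anchor point chosen
on the plane's ε = 0 line in the methyl region is taken as the low endpoint,
and the high endpoint lies 100 efficacy units along the plane gradient
(a, b)/(a² + b²). Any dataset interpolated between such endpoints satisfies
the plane exactly, so regression on generated data reproduces the generating
coefficients by construction. Remaining reporters get small, plausible
manual trajectories; multi-conformer reporters (M90 a/b/c, M178 a/b) carry
per-conformer fractions and state-dependent presence.

### Exchange broadening and the dynamics calibration

A literal two-site broadening law Rex = p(1−p)·Δω²/k_ex peaks at p = 0.5 and
cannot produce the observed pattern, in which full agonists are by far the
most broadened; the extra broadening comes from the pre-active state
sampling several substates (A′, A′′, …) in intermediate exchange. The
generator therefore parameterizes dynamics as a per-state-kind attenuation
curve f(state) ∈ (0, 1] — the relative height factor of a reporter:

- ligand/apo states: f = 0.55 − 0.38·(ε/100)^2.5 (flat ~0.55 band for apo
  and weak partials, dropping to 0.17–0.22 for full agonists; the exponent
  sets the onset of substate sampling),
- nanobody-only: f = 0.70,
- ternary complexes: f = 0.93 + 0.07·ε/100 (rigid, mildly efficacy
  dependent).

Each reporter scales this curve in log space by a sensitivity exponent
(M223/M296 = 1; M90 = 3, so a full agonist drives it below the detection
floor; references M153/M190/LMNG = 0, i.e. unbroadened). The attenuation is
converted to per-axis exchange broadening Rex = R₂·(f^(−1/2) − 1), applied
to both axes, which keeps heights, linewidths and volumes mutually
consistent (height ∝ 1/(fwhm_H·fwhm_C) at fixed volume). Peaks whose height
falls below 3× the noise sigma are emitted with `broadened_out`, reproducing
reporter loss in full-agonist spectra. Temperature scales the broadening as
exp((T − 308 K)/10 K) — cooling slows the substate exchange out of the
intermediate regime and sharpens the peaks — while an overall η(308)/η(T)
viscosity factor reduces absolute sensitivity at lower temperature. The
calibration constants were fixed once from the published pattern (ternary
≥ 0.9, apo/partial ≈ 0.5, full agonist ≈ 0.2 of the series maximum); the
ternary floor is set at 0.93 so the weakest ternary complex stays above 0.9
after fit noise.

### Rendering

Scenes are rendered as States-mode (hypercomplex) acquisitions: cosine- and
sine-modulated indirect datasets of exponentially damped sinusoids with
per-axis decay π·fwhm. Processing takes the direct-dimension absorption
before the indirect transform, giving pure-absorption 2D peaks; a plain
complex-complex path is retained for 1D-separable work and carries the usual
phase-twist. Peak amplitudes are normalized through the discrete windowed
decay sum Σ w(t)·e^(−rt) so every rendered peak's spectrum height equals its
ground-truth height exactly, independent of linewidth and apodization.
White Gaussian noise of configurable sigma is added to the processed
spectrum; all randomness flows through a single seed and rendering is
byte-identical for identical (configuration, seed).

## Acquisition, NUS and compressed sensing

The emulated experiment is a SOFAST ¹H,¹³C HMQC: 10,000 Hz sweep over 1024
direct points (defaults use 512 complex points, t_max 51.2 ms) and 4000 Hz
over 100 complex indirect points (t_max 25 ms) at an 800 MHz field.
Processing applies a squared-cosine window, zero-fills each axis to the
power of two at least 4× the acquired length (so window-limited peaks are
well sampled for fitting), Fourier-transforms and keeps the absorptive part;
only zero-order phase is relevant since synthetic data is generated
in-phase.

Poisson-gap schedules draw inter-sample gaps from Poisson distributions
whose mean follows a sine envelope across the grid (dense early sampling,
where the signal is largest); the gap scale is rescaled iteratively, with
sub-seed regeneration as a fallback, until the schedule holds exactly
round(fraction × total) indices, and index 0 is always sampled. The default
is 60 of 100 complex points.

IHT reconstruction iterates {FT the current estimate → zero components below
a decreasing threshold → inverse FT → restore measured points}. The
threshold decays geometrically from the initial maximum spectral magnitude
(decay 0.97, 200 iterations by default; both config-exposed, as the original
implementation's parameters are unpublished), and a final pass re-imposes
the measured increments, so data consistency at sampled points is exact.
For States data the reconstruction runs on the direct-dimension absorption
interferogram — the domain in which each indirect vector is sparse.

## Peak quantification

Picking takes local maxima above threshold·sigma (noise sigma from
1.4826·MAD over the lowest-variance corner tile unless a region is given),
deduplicated within a (0.05 ppm ¹H, 0.5 ppm ¹³C) ellipse. Peaks are
assigned to reporters by nearest ground-truth position within the same
tolerance ellipse, greedily by scaled distance, one peak per label.
Fitting refines center, amplitude and per-axis FWHM of a separable 2D
Lorentzian (Gaussian available) by least squares, jointly for peaks whose
(0.12, 1.0) ppm neighborhoods chain together; initial centers are snapped to
the nearby grid maximum so a guess a grid step off cannot strand the
optimizer in a broad-linewidth local minimum. Volumes use the model's
closed-form area (π²/4·A·fwhm_H·fwhm_C for the Lorentzian); "intensity"
throughout means fitted height, which is the more robust statistic when
linewidths are unreliable — volumes are kept for the titration path, which
genuinely integrates peaks.

Relative intensity is height(target)/height(reference) within one spectrum;
normalized intensity divides each reporter's relative intensities by their
series maximum (ties all map to 1; the operation is idempotent and invariant
to rescaling the spectrum). SNR values from different temperatures are
compared after multiplying by η(T)/η(T_ref) under a height ∝ 1/η model, with
η from the Vogel pure-water correlation (valid 273–373 K); buffer and
detergent contributions to viscosity are out of scope.

## Efficacy regression and populations

The plane fit is ordinary least squares of ε on (δ_H, δ_C, 1) with a centred
design for conditioning. ε is the response — matching the functional form
of the published fits — with no errors-in-variables treatment. Exactly
collinear shift pairs leave the plane unidentifiable; the minimum-norm
solution is returned with a `collinear` flag. The synthetic dataset
generator therefore adds small perpendicular (off-line) scatter to the
sampled shift pairs, emulating real off-axis residuals, while computing ε
exactly from the plane, so noiseless refits recover the generating
coefficients to machine precision.

Two-state populations are read from a shift pair by scalar projection onto
the endpoint axis in a standardized metric (0.1 ppm ¹H ≡ 1.0 ppm ¹³C,
typical linewidth scales, so neither axis dominates); the perpendicular
residual is reported as off-axis distance and out-of-range projections are
clipped with a flag. The χ³ rotamer classifier uses literature-convention
thresholds (gauche < 15.5 ppm, trans > 17.0 ppm, ambiguous between),
config-exposed; only the efficacy-responsive conformer of M178 is fitted.

## Binding

`fraction_bound` solves the 1:1 quadratic exactly, in the 2RL/(s + √·) form
that is stable at extreme concentration ratios. K_d estimation fits observed
bound fractions volume_bound/(volume_bound + volume_free) — a ratio formed
within one spectrum, cancelling per-spectrum scaling — against the isotherm
over log K_d (bounds 10⁻³–10⁵ μM), with a percentile bootstrap over
titration points for the confidence interval. The receptor concentration is
taken from configuration (default 100 μM with an 8-point titrant series
10–1500 μM, stand-ins since the experimental values are not printed); a
noiseless series is recovered to optimizer precision, and 5% multiplicative
volume noise yields a median K_d error of a few percent.

## What the generator does and does not emulate

The generator reproduces: efficacy-dependent fast-exchange shift
trajectories on both equilibrium axes; state-dependent intermediate-exchange
broadening including reporter loss; multi-conformer reporters; slow-exchange
free/bound titration volumes; NUS/CS acquisition; temperature effects on
broadening and sensitivity. It does not emulate: real assignment ambiguity
(labels are known), buffer/detergent background beyond a single LMNG
reference peak, field-dependent relaxation, >2-site lineshape kinetics for
M90, or errors-in-variables in the shift measurement. Passing tests
therefore validate the estimators and the pipeline plumbing under the
stated model, not the model's fidelity to any particular receptor. The
thermostabilised-mutant scenario is a configuration preset (left-shifted
equilibria, reduced broadening), not a separate code path.

## Numerical choices

- Bloch–McConnell systems are validated for population normalization,
  zero column sums and stationarity to 10⁻⁶ relative; singular frequency
  points are regularized with infinitesimal extra damping, never returned
  non-finite.
- Exchange-regime thresholds default to k_ex/|Δω| < 0.1 (slow) and > 10
  (fast) — the conventional decade separation around coalescence, flagged
  as a convention rather than a measured boundary.
- Coalescence counting uses local maxima above 5% of the global maximum.
- The 2D rendering composes two 1D axes (outer product); multiple-quantum
  relaxation pathways of the HMQC are not modeled.
- Noise is added in the frequency domain, making the spectrum's noise sigma
  the configured value directly.
- Seeds: every stochastic operation takes an explicit integer seed; derived
  sub-seeds stay below 2³¹.
- Default problem sizes (512×100-point acquisitions, 200 IHT iterations,
  200-seed Monte-Carlo loops, 200 bootstrap resamples) keep any single
  analysis in the seconds-to-a-minute range.

## Known limitations

Fitted Lorentzian amplitudes on windowed, truncation-limited peaks carry a
few percent of model mismatch; ratios between peaks of similar width cancel
most of it, which is one reason the reference-relative intensity statistic
is robust. The Poisson-gap rescaling loop is heuristic (though
exact-count by construction). The IHT threshold schedule is a tunable, not
a published value. Plane refits from data with little off-line scatter are
ill-conditioned by nature; the collinearity flag should be checked before
interpreting coefficients from narrow trajectories.
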