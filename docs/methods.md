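# Methods

This note records the models implemented by `infantfc`, the defaults and
why they hold, what the synthetic generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Signal model and preprocessing

A continuous-wave fNIRS channel records intensity at two wavelengths
(780/850 nm) at 10 Hz. Attenuation changes are expressed as optical density
`ΔOD = −ln(I/⟨I⟩)`; dividing by the temporal mean makes the measure
invariant to source power and detector gain, at the cost of an arbitrary
additive constant per channel (irrelevant for correlation-based FC — the
forward/inverse round-trip tests therefore compare *demeaned* series).

The stage order is fixed: prune → OD → band-pass 0.009–3 Hz → global
signal regression (GSR) → band-pass 0.009–0.08 Hz → GVTD censoring →
modified Beer–Lambert → section averaging. GSR operates on OD with one
array-mean regressor per wavelength (the pooled-regressor alternative was
rejected because the two wavelengths weight HbO₂/HHb differently, so their
systemic components differ by a scale factor that a pooled regressor cannot
absorb). GSR is an ordinary least-squares projection and hence idempotent.

**Filters.** Zero-phase forward–backward Butterworth, order 3 per pass.
The 0.009 Hz high-pass edge has an impulse response of order 1/0.009 ≈
100 s; `sosfiltfilt`'s default edge padding is far too short for it and
produces large shared edge transients, so the padding is set explicitly to
3·fs/low_hz samples. Filter order and band edges are config-exposed
(`RunConfig.band_wide_hz`, `band_narrow_hz`).

**GVTD censoring.** GVTD(t) is the RMS across channels of the one-sample
temporal derivative. The censoring threshold is the distribution mode
(kernel-density maximum over a 512-point grid; median fallback for
degenerate inputs) plus 5 × the RMS deviation of the sub-mode values — the
left half of the distribution estimates the motion-free floor, so the
spread statistic is one-sided by construction. The multiplier (default 5)
and the mode estimator are config-exposed. Censoring masks ±5 s around
every exceedance and keeps only valid runs ≥ 20 s; masked samples are
never interpolated — all downstream correlation uses the concatenated
valid samples.

**MBLL.** Per channel the 2×2 linear system in (ΔHbO₂, ΔHHb) is solved
sample-wise with molar extinction coefficients from a packaged compilation
(cm⁻¹/M, linearly interpolated over 690–900 nm) and the general age- and
wavelength-dependent differential pathlength factor

    DPF(λ, A) = 223.3 + 0.05624·A^0.8493 − 5.723e-7·λ³ + 0.001245·λ² − 0.9025·λ

(A in years, λ in nm). Evaluated at the study ages this gives
5.25/4.25 (5 mo), 5.26/4.26 (8 mo), 5.28/4.28 (12 mo), 5.30/4.30 (18 mo),
5.32/4.33 (24 mo) for 780/850 nm, each rounded to two decimals.

**Channel quality.** SCI is the zero-lag Pearson correlation of the
cardiac-band (0.5–2.5 Hz, a physiological range for infant heart rates plus
margin) filtered, standardized wavelength pair; PSP is the peak of the
Hamming-windowed power spectrum of their normalized cross-correlation
within the cardiac band, invariant to common amplitude rescaling. Windows
are non-overlapping 3 s blocks (stride config-exposed); the cardiac filter
is applied once to the full series before windowing. Zero-variance
(dead/saturated) windows score NaN and count as failures. Exclusion
requires *both* scores below threshold (SCI < 0.70, PSP < 0.1) in > 70% of
windows; a recording is dropped when > 40% of channels are excluded. The
vectorized whole-recording scorer is asserted equal to the per-window
definitions in the test suite.

## Probe model and displacement renumbering

The packaged `bright_infant` fixture is a two-band layout: per hemisphere
7 sources and 6 detectors in two staggered rows yielding 17 channels at
exactly 2 cm separation, ordered anterior → posterior and grouped into
front (6), middle (6) and back (5) sections. When the recorded lateral
displacement of the reference optode is ≥ 1.6 cm, every channel takes the
section of the adjacent chain position in the compensating direction;
channels shifted past a band end become unassigned and drop out of section
averages, and shifts never cross the midline. Sign convention (flagged
because the direction is not externally fixed): positive displacement
means the band sat anterior of ideal, so channels inherit the section of
the preceding (more anterior) chain position.

## Connectivity

Section series are means of surviving channels; a section left without
channels propagates as NaN through its matrix entries. Pearson
correlations are computed on concatenated valid samples (a per-chunk mode
is available as config), r is clipped to ±(1−1e−7) before `atanh` to keep
z finite. Of the 15 unordered section pairs, 3 are interhemispheric
homotopic, 6 intrahemispheric and 6 crossed; front↔back pairs additionally
carry a `fronto_posterior` (long-range) flag. An `include_diagonal` option
appends the 6 self-pairs for a 21-entry enumeration, and the Bonferroni
divisor is configurable independently of the enumerated set, because
6 sections yield 15 informative pairs while some reporting conventions
count 21. Subjects need ≥ 250 s of valid data; the split-half stability
curve (first k vs last k valid seconds, correlating vectorized upper
triangles) shows why: on default-scenario simulations mean stability rises
from ≈ 0.47 at 60 s to ≈ 0.85 at 250 s.

## Synthetic recordings

The generator inverts the pipeline's own forward model. Components:

- **Slow section hemodynamics**: 6 series with a prescribed covariance,
  synthesized exactly band-limited to 0.009–0.08 Hz in the frequency
  domain (no filter transients, rows independent by construction). The
  default covariance is a developmental-pattern correlation matrix
  (homotopic positive ≈ 0.45–0.55, fronto-middle anticorrelated ≈ −0.35)
  scaled to 0.5 µM and projected by P = I − 11ᵀ/6 onto the zero-array-mean
  subspace. The projection encodes the assumption under which GSR is
  valid — the array mean carries only the systemic signal — and makes the
  generator's ground truth recoverable by a GSR-based pipeline. Passing
  tests therefore certify the pipeline *given* that assumption; they say
  nothing about GSR-induced distortion when regional signals do load on
  the array mean, which real data may exhibit.
- **HHb** is −0.5 × HbO₂ per section (typical amplitude ratio and
  anticorrelation; both chromophores then share one FC structure, as
  observed empirically).
- **Systemic global signal**: one band-limited series, sd 1.0 µM, added to
  every channel (systemic physiology is commonly of the same order as or
  larger than the cortical signal, which is the motivation for GSR).
- **Cardiac pulsation**: a 2.2 Hz (infant ≈ 130 bpm) sinusoid with slow
  random phase drift, common across channels, scaled by a per-channel
  coupling amplitude (default 0.01 OD; 0 models a decoupled optode) and a
  wavelength gain pair (0.8, 1.2) reflecting the arterial HbO₂ weighting.
- **Motion events**: Hann-shaped OD transients with random sign and scale
  per channel (default three events of 2 s, 0.3 OD — an order of magnitude
  above the hemodynamic OD amplitude, as typical of infant headgear
  motion). Amplitude matters: a transient much below ≈ 0.1 OD has too
  little energy below 0.08 Hz to be visible to GVTD computed after the
  narrow band-pass. Baseline shifts are supported
  (`motion_shift_fraction`) but default to 0: a step passed through the
  0.009 Hz high-pass becomes a ≈ 100 s transient that no ±5 s censoring
  can contain, so enabling shifts contaminates every recording by
  construction.
- **Measurement noise**: white OD noise, sd 0.003 per wavelength.
- Intensities are I₀·exp(−OD) with I₀ = 1 (scale-free through the OD
  log-ratio).

Ground truth records the section series, the global signal, the artifact
sample mask, per-channel coupling flags, and both the population
correlation (from the covariance) and the realized correlation of the
generated series. **Recovery error is defined against the realized
correlation over the same valid samples the pipeline used**: 600 s of a
0.071 Hz-bandwidth process contains only ≈ 85 effective samples, so the
realized correlation of a single run differs from the population value by
≈ 0.11 in z purely by sampling; comparing against the realized truth
isolates pipeline-induced error (filters, GSR, censoring, MBLL) from that
scenario-intrinsic variability. Under the default scenario the pipeline's
mean |ẑ − z_true| over the 15 pairs is ≈ 0.07.

What the generator does **not** emulate: photon transport and partial
volume effects (channel chromophore series are section values, not depth-
weighted mixtures), respiration and Mayer waves as distinct spectral
peaks, heteroscedastic or 1/f instrument noise, slow drifts, wavelength-
dependent coupling loss, and spatially graded motion (all channels share
each event, with random sign). Conclusions from passing tests transfer to
real data only to the extent these simplifications are immaterial to the
stage under test.

## Synthetic cohorts

Connection-wise Fisher-z trajectories: z = baseline + age-level change +
random intercept (sd 0.15) + AR(1) residual (sd 0.25, ρ = 0.3 across the
five visit ranks), with visits missing completely at random (default 0.4,
giving ≈ 132 of 204 infants with ≥ 2 visits as in band-style longitudinal
cohorts; n_subjects defaults to 132). Default fixed effects mirror a
developmental pattern: frontal interhemispheric FC starting at +0.28 and
declining by −0.33 over 5→24 months; left/right fronto-middle and right
fronto-posterior FC starting negative and rising by ≈ +0.2. Growth: WLZ is
a stable between-infant level (mean −0.3, sd 0.7) plus a visit-to-visit
random walk (step sd 0.35); prescribed ΔWLZ→FC couplings add
slope·(ΔWLZ − mean) to the 24-month value of the named connection
(defaults: +0.30 on frontal interhemispheric, −0.20 on left fronto-middle,
both over birth→24 mo). Outcomes: cognitive-flexibility scores (intercept
6, noise sd 2) with prescribed FC→score slopes per preschool group.
Everything is seed-deterministic.

## Statistics

**FC vs age.** Age is categorical (the per-age change estimates force
this; a continuous-age mode is available through the design matrix).
The covariance of a subject's visits is σ_b² + σ_e²·ρ^|rank difference|,
with rank the position in the canonical visit schedule, so a skipped visit
widens the gap. Estimation is REML: fixed effects are profiled out by GLS;
the three variance parameters (log σ_b², log σ_e², atanh ρ) are optimized
by Nelder–Mead, with subjects grouped by visit pattern so each pattern
costs one Cholesky per evaluation. The age effect is a Wald F with
residual denominator degrees of freedom (N − p); at the cohort sizes in
scope (≥ 40 subjects, ≈ 3 visits each) its null rejection rate is
empirically ≈ 0.05 (500-replicate simulation in the acceptance suite), so
no small-sample df correction (Satterthwaite/Kenward–Roger) is applied.
Only subjects with ≥ 2 valid visits enter. With ρ fixed at 0 the model is
a random-intercept LMM and matches `statsmodels MixedLM` (REML) to 1e-4 on
fixed effects; with both variance components at zero GLS reduces exactly
to OLS — both checks are in the test suite.

**Growth and outcome regressions** are ordinary least squares
(statsmodels); the reported F is the partial F (t²) of the predictor with
(1, N−p) df, matching simple-regression reporting. Regressions are gated
on connections whose FC changed significantly with age (Bonferroni), run
for all 21 ΔWLZ intervals, reported unadjusted and adjusted (birth WLZ or
7/14-day HCZ) side by side, and FDR-corrected per connection
(Benjamini–Hochberg via statsmodels, validated against hand-computed
step-up examples). ΔWLZ is later − earlier (positive = relative growth
gain); the opposite literal convention exists in the field, so the sign is
stated in the docstring and here.

**LMS z-scores** use z = ((x/M)^L − 1)/(L·S), with |L| < 1e-4 evaluated in
the log-form limit (the analytic branch difference is O(L·ln²(x/M)),
≈ 1e-5 at the switch point) and `expm1` for small-L stability; table keys
are linearly interpolated. The packaged reference table is synthetic
(smooth plausible curves, labelled as such); real WHO tables drop in
through the same CSV schema.

## Problem sizes in the test and acceptance suites

Chosen as the package's own verification design: FC recovery uses 100
replicates of the default 600 s scenario; QC discrimination uses 5 seeded
300 s recordings (500 windows) with 8 of 34 channels decoupled; LMM checks
use 200 recovery replicates at 60 subjects and 500 null replicates at 40
subjects; FDR control uses 1000 replicates of 21 independent nulls;
covariance convergence uses a single 2000 s realization (mean absolute
deviation over pairs, since a per-entry bound would be dominated by the
≈ 0.06 sampling SE of a single entry).

## Known limitations

- The AR(1) distance is visit rank, not days; a days-based metric is a
  straightforward extension of the covariance builder.
- GVTD after the 0.009–0.08 Hz band-pass (the pipeline's stage order) is
  blind to short transients below ≈ 0.1 OD; censoring quality is therefore
  tied to artifact magnitude.
- The Wald F's residual-df calibration was verified for the cohort sizes
  above; very small cohorts (≪ 40 subjects) may need exact small-sample
  corrections.
- Section averaging assumes the fixture's channel→section map; no
  subject-specific co-registration is performed, and the displacement
  renumbering is a one-slot approximation along the band.
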