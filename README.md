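# infantfc

Infant fNIRS resting-state functional connectivity, from raw two-wavelength
intensity signals to section-level Fisher-z connectivity matrices and the
longitudinal statistics that relate connectivity to age, early growth, and
preschool cognitive outcome.

The package is written for developmental-neuroimaging researchers working
with longitudinal infant fNIRS cohorts — in particular band-style headgear
arrays (here: 14 sources, 12 detectors, 34 channels at 2 cm separation,
780/850 nm, 10 Hz) in settings where undernutrition and other early
adversity may alter the maturation of functional brain networks. Because
such cohort data are rarely openly shareable, the package ships a
first-class synthetic-data generator that produces raw recordings and whole
longitudinal cohorts with known ground truth, so every stage of the
pipeline is testable end to end.

## The pipeline

Per recording (stage order is fixed):

1. **Channel quality.** The cardiac pulsation recorded by a well-coupled
   optode appears at both wavelengths. In non-overlapping 3 s windows, the
   scalp coupling index `SCI = corr(x₇₈₀, x₈₅₀)` of the cardiac-band
   (0.5–2.5 Hz) filtered, unit-variance signals, and the peak spectral
   power `PSP` of their normalized cross-correlation, are computed per
   channel. A channel is pruned when *both* SCI < 0.70 and PSP < 0.1 in
   more than 70% of windows; a recording is excluded when more than 40% of
   channels are pruned.
2. **Optical density.** `ΔOD(t) = −ln(I(t)/⟨I⟩)` per channel and wavelength.
3. **Filtering and systemic-signal removal.** Zero-phase Butterworth
   band-pass 0.009–3 Hz, then global signal regression (each channel's
   least-squares residual from the array-mean time course, per wavelength),
   then band-pass 0.009–0.08 Hz.
4. **Motion censoring.** `GVTD(t) = √(meanᵢ (yᵢ(t) − yᵢ(t−1))²)` across
   channels; samples where GVTD exceeds *mode + 5 × sub-mode spread* are
   artifacts. ±5 s around every artifact is masked and only valid runs of
   ≥ 20 s are retained.
5. **Haemoglobin conversion.** Modified Beer–Lambert law: per channel the
   2×2 system `ΔOD_λ = (ε_HbO₂,λ·ΔHbO₂ + ε_HHb,λ·ΔHHb)·d·DPF(λ, age)` is
   solved sample-wise, with the differential pathlength factor from the
   general age/wavelength equation
   `DPF(λ, A) = 223.3 + 0.05624·A^0.8493 − 5.723×10⁻⁷λ³ + 0.001245λ² − 0.9025λ`.
6. **Section FC.** Surviving channels are averaged into six sections
   (left/right × front/middle/back; 17 channels per hemisphere). Pearson
   correlations between section series over the concatenated valid chunks
   give a 6×6 matrix, Fisher-z transformed (`z = atanh r`). Recordings with
   less than 250 s of valid data are excluded; a split-half stability curve
   (`stability_curve`) motivates that threshold.

Per cohort:

- **FC vs age:** per connection, `z_ij = β₀ + Σ_k β_k·1[age=k] + b_i + ε_ij`
  with a random intercept per infant and AR(1) residual correlation across
  ordered visits, fitted by REML; Wald F on the age indicators; Bonferroni
  control across connections.
- **Growth → FC:** WHO-style LMS z-scores (`z = ((x/M)^L − 1)/(L·S)`),
  ΔWLZ = WLZ(later) − WLZ(earlier) over all 21 visit intervals, OLS of
  24-month FC on each ΔWLZ (optionally adjusted for birth WLZ or 7/14-day
  HCZ), Benjamini–Hochberg FDR per connection.
- **FC → outcome:** OLS of preschool cognitive-flexibility scores on FC at
  each age, per preschool age group.

## Worked example

```sh
python examples/cohort_statistics.py
```

simulates 132 infants (five visit ages, 40% missing visits, random
intercepts, AR(1) ρ = 0.3) and runs the three analyses. Output:

```
connections whose FC changed significantly with age (Bonferroni p < 0.00333):
  L-front|L-middle   F= 9.04  p=5.55e-07  baseline=-0.32  5->24 change=+0.22 (0.05)
  L-front|R-front    F=16.07  p=3.73e-12  baseline=+0.28  5->24 change=-0.32 (0.04)
  R-front|R-middle   F=12.47  p=1.57e-09  baseline=-0.29  5->24 change=+0.22 (0.04)
  R-front|R-back     F= 6.23  p=7.29e-05  baseline=-0.21  5->24 change=+0.19 (0.04)

ΔWLZ intervals predicting FC at 24 months (FDR-significant, 24 of 84 tests):
  L-front|L-middle   ΔWLZ birth→ 8mo: F(1,71)=5.88, p=0.018 (FDR 0.038), R²=0.076, slope -0.12
  ...
```

The generating truth (frontal interhemispheric FC declining from +0.28 by
−0.33 over 5→24 months; early ΔWLZ raising 24-month interhemispheric FC
with slope +0.30 and lowering fronto-middle FC with slope −0.20) is
recovered with correct signs and magnitudes. The other examples cover
single-recording FC recovery (`simulate_and_recover_fc.py`), channel
pruning (`channel_quality.py`), growth z-scores (`growth_zscores.py`), and
the stability analysis (`stability_analysis.py`).

A thin CLI wraps the same calls:

```sh
infantfc simulate --out scratch/sim --n-recordings 3 --cohort --seed 1
infantfc qc scratch/sim/sim-001.snirf
infantfc fc scratch/sim/*.snirf --out scratch/fc
infantfc run-all --out scratch/reports --seed 1
```

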