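# Methods

## Measurement model

The forced-oscillation exam is modelled as a linear time-invariant
single-input system: a multisine pressure excitation applied at the mouth
drives oscillatory flow through the respiratory input impedance `Zrs(f)`.
The synthesis is the steady-state phasor solution — for each excitation
component the flow amplitude is `|P|/|Z|` and the flow phase lags the
pressure by `arg Z`.  The sign convention is inertial-positive:
`X(f) = 2πfI − 1/(2πfC)`, so pressure leads flow where inertance dominates
and lags where compliance dominates, and the resonance
`fr = 1/(2π√(IC))` is the zero crossing.

Mechanical variants: a pure resistor (oracle), a series R–I–C branch, an
extended branch with `Re Z(f) = R + S·f` (the resistance slope `S` imposed
directly), and two R–I–C branches in parallel.  A single series branch has a
frequency-flat resistance, so it cannot produce the negative frequency
dependence of resistance seen in obstructed/heterogeneous lungs; the
extended branch encodes that dependence in a directly controllable way
(useful for recovery tests), while the parallel topology produces it
mechanistically.  Neither is a claim about disease physiology — they are
surrogates with known ground truth.  For an extended branch with `S < 0`
model validation additionally requires `R + 32·S > 0` so the resistance
stays positive across the excited band.

## Excitation, disturbances and their defaults

* Components 4, 6, …, 32 Hz (15 tones), sampling 1024 Hz, 16 s records,
  2 cmH₂O peak-to-peak — the study's measurement protocol.  Tones are
  required to sit on the `fs/4096 = 0.25 Hz` analysis-bin grid; the 2 Hz
  tone spacing leaves 8 bins between neighbours, so block FFTs see each
  tone leakage-free.  Phases are seeded uniform draws ("pseudorandom
  multisine"); equal amplitudes are rescaled after phase drawing so the
  peak-to-peak value is met exactly.
* Breathing: a single 0.25 Hz flow sinusoid of 0.4 L/s amplitude plus its
  Ohmic pressure response (`Re Z` at the breathing frequency).  This is the
  simplest disturbance that stresses the coherence gate and the detrending
  without claiming physiological fidelity: real breathing is non-sinusoidal,
  amplitude-modulated and spectrally broader.
* Sensor noise: independent white Gaussian noise, 0.05 cmH₂O and
  0.02 L/s RMS on the pressure and flow channels.  Chosen once as a
  realistic bench noise floor relative to the ~0.13 cmH₂O per-tone
  amplitude; at these levels per-exam coherence stays ≈ 0.999 and the
  median impedance error is below 2 %, consistent with an exam that
  routinely passes the γ² ≥ 0.9 gate as clinical exams do.

## Cohort calibration

Groups: 23 controls, 21 patients with normal spirometry (NE), 24 with
abnormal/restrictive spirometry (AE); three exams per subject, averaged.
Each subject is an extended-branch model with independent truncated-normal
parameters (`R > 0.1`, `C > 0.001`, `I ≥ 0`; up to 100 redraws, then an
error).  The only published anchors are the control and AE resistances
(2.77 ± 0.23 and 3.91 ± 0.57 cmH₂O·s/L).  The remaining means/SDs are
calibration choices fixed at design time:

| group   | R (cmH₂O·s/L) | S (per Hz)      | I (cmH₂O·s²/L) | C (L/cmH₂O)   |
|---------|---------------|-----------------|----------------|----------------|
| control | 2.77 ± 0.23   | −0.010 ± 0.010  | 0.010 ± 0.0015 | 0.020 ± 0.003  |
| NE      | 3.00 ± 0.40   | −0.035 ± 0.015  | 0.010 ± 0.0015 | 0.017 ± 0.003  |
| AE      | 3.91 ± 0.57   | −0.060 ± 0.020  | 0.010 ± 0.0015 | 0.011 ± 0.0025 |

Rationale: resistance rises with disease; the slope grows more negative
(ventilation heterogeneity) already in NE; compliance falls with
restriction, which simultaneously raises `fr` (≈ 11 Hz control → ≈ 16 Hz AE)
and lowers `Cdyn` — reproducing the qualitative group ordering of the
study's resistive and reactive parameters.  Passing tests on this cohort
demonstrate that the *machinery* behaves correctly under a calibrated,
idealized population; they do not certify accuracy on real patients, whose
impedance contains nonlinearity, upper-airway shunt, leaks and
within-breath variation that the generator deliberately omits.

## Impedance estimation

Welch-averaged auto/cross spectra over 4096-sample blocks with 50 %
overlap (7 blocks per record); flow-referenced H1 estimator
`Ẑ = Gqp/Gqq` (robust to pressure-channel noise uncorrelated with flow; the
choice of estimator form is ours — only the block scheme is prescribed).
Default Hann taper with per-block linear detrend suppresses breathing
leakage into the 4 Hz bin (worst-case bias ~10⁻⁴ relative); the
rectangular/no-detrend combination is exact for bin-aligned noiseless
signals and is what the forward oracles use.  Coherence
`γ² = |Gpq|²/(Gpp·Gqq)` gates quality at γ² ≥ 0.9 (inclusive).  A failed
component fails the whole exam (one adequacy criterion per measurement);
per-frequency flags are retained, and downstream extraction honours them,
so per-frequency rejection is available by skipping the exam-level gate.
Subject values are the complex mean of Z over the (up to three) passing
exams; zero passing exams raises a subject-level QC failure.

## Parameter extraction choices

* `Xm` averages X over the full 4–32 Hz band (the measured band; the
  source protocol does not state a sub-band).  Configurable.
* `fr` by linear interpolation between the bracketing grid points; with
  multiple crossings the first from below is taken; all-negative reactance
  extrapolates from the last two points and flags the value.  On the 2 Hz
  grid interpolation bias is ≈ 0.04 Hz for typical curvature.
* `Cdyn = −1/(2π·4·X(4))` from the lowest measured frequency — the standard
  low-frequency compliance estimate.  Note `Cdyn ≠ C` even noiselessly,
  because inertance contributes to X(4) (for R=2.77, I=0.01, C=0.02:
  X(4) = −1.738, Cdyn = 0.0229).  Undefined (flagged, not an exception)
  when X(4) ≥ 0.
* `S` is reported as the raw OLS slope in cmH₂O·s/L per Hz.  Published
  cut-off tables for this parameter print values (≈ −15) implying a
  different display scale that is not documented anywhere we could verify;
  we do not guess — the raw slope is canonical and any display scaling is
  left to configuration.

## Statistics and diagnostic accuracy

* Normality gate: Shapiro–Wilk per group (comparisons) or per variable
  (correlations) at α = 0.05 (the gate level is not stated in the source
  protocol; 0.05 is the conventional choice).  Degenerate (constant)
  samples route to the non-parametric branch.  Pairwise Tukey /
  Mann–Whitney p-values are reported raw; only correlations receive the
  modified Bonferroni level (effective independent correlations =
  resistive/reactive axes × comparator variables; 2 × 4 → 0.05/8 = 0.0063
  as reported, rounded half-up to 4 decimals with the raw value used for
  decisions).
* Correlation bands overlap at their printed endpoints; edges are assigned
  to the higher band, symmetrically in sign.
* AUC by Mann–Whitney pair counting (ties 0.5), identical to the
  trapezoidal area under the empirical curve; curves auto-orient so
  AUC ≥ 0.5 and record the orientation.  Optimal cut-off maximizes the
  Youden index; ties break toward higher specificity, then lower
  threshold (no criterion is named in the source protocol; Youden is the
  standard choice).  Accuracy bands are closed on the left (0.70 →
  moderate, 0.90 → high); adequacy at AUC ≥ 0.75.
* Sample size: Hanley–McNeil normal-approximation test of an AUC against a
  null value, with the large-sample variance slope
  `v(A) = Q1 + Q2 − 2A²`, `Q1 = A/(2−A)`, `Q2 = 2A²/(1+A)`, equal groups:
  smallest n with `z_α√(v0/n) + z_β√(v1/n) ≤ A1 − A0`.  Sidedness is a
  flag; the two-sided default reproduces the clinical-software convention
  (20 per group for 0.75 vs 0.5 at α = β = 0.10; one-sided gives 15).
  Confidence intervals use the exact finite-sample Hanley–McNeil SE.

## Decision support

Classifier defaults (none are prescribed by the source protocol):
SVM C = 1 (RBF γ = 1/(p·var)); k-NN k = 5; random forest 500 trees;
AdaBoost 100 stumps; Parzen bandwidth per feature by Silverman's rule on
the pooled training fold.  Features are z-scored inside each training fold
(distance- and kernel-based methods require a common scale).  Evaluation
pools out-of-fold scores from stratified 10-fold CV (seeded) or LOOCV and
reports AUC plus Se/Sp at the pooled Youden cut-off.  Exhaustive search
enumerates all `2^p − 1` subsets (guarded at p ≤ 20) and breaks AUC ties
toward smaller subsets, then lexicographic order.  The search runs
*outside* the CV loop — the winner is selected on the same folds it is
scored on — which is optimistically biased on small samples; nesting the
search would remove the bias at ~p·2^p times the cost and is left to the
caller by evaluating the chosen subset on fresh seeds.

## Numerical and engineering notes

* All randomness flows from explicit integer seeds; cohorts are
  reproducible per `(master_seed, subject index)`, records bit-identical
  under regeneration; pipeline artifacts are checksum-stable given a
  config.
* Degenerate inputs: zero flow auto-spectrum, off-grid components,
  single-class score sets, zero-variance correlation inputs and infeasible
  cohort draws all raise typed exceptions rather than propagating NaNs;
  undefined `Cdyn`/`fr` are flags, since they occur in legitimate data.
* Problem sizes used by the test suite (100-subject recovery runs, 200
  CV permutations, 10⁴-per-group binormal check, full 68-subject demo)
  were chosen so the whole suite completes in about a minute on one core
  while keeping Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The generator omits nonlinear (flow-dependent) resistance, glottal and
  leak artifacts, cheek shunt, and within-breath impedance variation.
* Breathing is a pure bin-aligned sinusoid; real breathing stresses the
  coherence gate harder than the simulation does.
* The two-compartment model's resonance has no closed form here; use the
  numeric zero crossing.
* Group-difference and classifier results on synthetic cohorts quantify
  machinery correctness, not clinical effect sizes.
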