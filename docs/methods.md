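# Methods

## Problem and pipeline

`mltriss` estimates the two clinical severity labels used by trauma scoring
systems — the Glasgow Coma Scale (GCS, integers 3–15) and the Injury
Severity Score (ISS, integers 1–75) — from features of the first 15 minutes
of continuous physiologic monitoring after admission, then substitutes those
estimates into the Revised Trauma Score (RTS) and the TRISS survival model
and measures how well the resulting scores discriminate in-hospital
mortality.  The pipeline has six stages:

1. **simulate** – generate a synthetic cohort with physiologically coupled
   signals (see below);
2. **preprocess** – physiologic range filter, 30 s centered median filter on
   the 0.5 Hz numeric channels, robust DCT-penalized smoothing of the
   240 Hz waveforms, 15-minute admission window with a 5-minute minimum
   coverage rule (inclusive);
3. **features** – descriptive statistics, threshold-dose features, shock
   index, and HRV time-, frequency-, and nonlinear-domain features from both
   ECG- and PPG-derived beat series;
4. **train** – ML-GCS (13-class classification) and ML-ISS (regression) with
   inverse-category-frequency case weights and randomized-search
   cross-validated tuning;
5. **score** – assemble four score panels per patient: real RTS/TRISS,
   ML-RTS (ML-GCS substituted), ML-TRISS (ML-ISS with real GCS), ML-TRISS2
   (both estimates);
6. **evaluate** – one-vs-rest multiclass AUCs (macro/micro), category-level
   confusion matrices, mortality AUROCs with DeLong confidence intervals,
   and operating metrics at the Youden-optimal threshold, per subgroup
   (all, polyTBI: head AIS ≥ 1, isoTBI: head AIS ≥ 1 and other AIS ≤ 1).

## Scoring formulas

RTS = 0.9368·G + 0.7326·S + 0.2908·R over coded points G, S, R ∈ {0..4}
(GCS: 3→0, 4–5→1, 6–8→2, 9–12→3, 13–15→4; SBP: 0→0, 1–49→1, 50–75→2,
76–89→3, >89→4; RR: 0→0, 1–5→1, 6–9→2, 10–29→4, >29→3).  TRISS survival is
logistic(b) with b = b₀ + b_RTS·RTS + b_ISS·ISS + b_age·1{age ≥ 55}, blunt
coefficients (−0.4499, 0.8085, −0.0835, −1.743) and penetrating
(−2.5355, 0.9934, −0.0651, −1.136).  These constants are treated as fixed;
no recalibration is in scope.  ML-ISS enters the linear predictor clamped to
[1, 75] and unrounded (the model is linear in ISS, so rounding only loses
information).  SBP and RR points are coded from the median of the cleaned
first-15-minute series; which snapshot fed the original scores is unknown,
and the median is the most artifact-tolerant choice.

## Synthetic cohort generator

The generator is the package's study condition, not a fixture.  Each
patient carries a latent severity s ~ N(0,1).

* **Labels.**  The GCS latent is a noisy copy of s (equal parts signal and
  noise at the default coupling); category thresholds on it reproduce the
  configured mild/moderate/severe mix exactly (default 88.5 / 3.7 / 7.8%).
  Within-category integer masses are shaped like real admission cohorts
  (median 15, IQR [14, 15]; GCS 3 carries ~45% of the severe bin) rather
  than uniform — a uniform fill makes exact-GCS classification artificially
  hopeless for the severe values.  The ISS latent mixes s with its own
  noise at a weight giving a GCS–ISS association of |r| ≈ 0.4, and maps
  through a log-normal transform calibrated to the mild/moderate/severe/
  profound bin fractions (≈ 55/25/11/9%).  ISS is floored at max(AIS)²,
  the anatomic constraint implied by its definition.
* **Physiology.**  Heart rate rises and SDNN / HF modulation fall linearly
  in s (autonomic dysfunction tracks neuro status).  Baseline pressures and
  transient hypotensive episodes additionally track a hemorrhage driver
  that shares a component with the ISS latent, so minimum MBP carries
  ISS-specific information no HRV feature has.  Episode nadirs grow
  supra-linearly with that driver (profound injury means frank hypotension,
  MBP nadirs in the 40–60 mmHg range) and pull the pressures toward an
  absolute severity-determined floor rather than subtracting a fixed depth
  from the patient's baseline; episode count and duration vary freely, and
  a severity-independent slow pressure wander is superimposed, so window
  SDs carry shape randomness while the minimum stays the clean severity
  marker.  Desaturation couples to a chest-injury latent only weakly linked
  to overall ISS; pulse-ox and displayed SBP/DBP numerics get higher noise
  than the monitor-computed MBP.  All couplings scale with
  `severity_coupling` (default 1.0); at 0 the signals are independent of
  the labels.
* **Signals.**  Numeric channels (HR, SpO2, SBP, DBP, MBP, RR) at 0.5 Hz;
  ECG and PPG at 240 Hz rendered template-wise (Gaussian QRS-like bump per
  beat; raised-cosine pulse at a fixed 200 ms delay).  The monitor HR
  channel is derived from the generated RR series.  RR-interval modulation
  mixes an LF tone (0.095 Hz), an HF tone (0.275 Hz) and white beat-to-beat
  noise with configurable variance fractions.
* **Outcome.**  Mortality is Bernoulli(1 − TRISS survival) computed from
  the true GCS/ISS/age/mechanism, with RTS points taken from the baseline
  SBP and RR setpoints.  The cohort's mortality process is therefore
  exactly the scoring model under evaluation; the TRISS AUROC measured on
  the cohort approaches the ceiling imposed by the risk distribution
  (≈ 0.91 at the default conditions), not 1.0.

What the generator does **not** emulate: realistic ECG/PPG morphology
(P/T waves, arrhythmia, pulse-wave shape), sensor dropouts and motion
artifact beyond additive noise, drug effects (sedation, paralytics) that
decouple GCS from physiology, and registry-style AIS coding variation.
Passing tests therefore demonstrate the pipeline's internal correctness and
the recoverability of severity under the stated coupling assumptions — not
clinical performance on real monitor data.

## Preprocessing details

* **Range filter.**  Upper bounds HR 200 bpm, SBP 250 mmHg, DBP 200 mmHg
  (sensor-range rule); SpO2 capped at 100%; lower bounds default to 0.
  Out-of-range samples become explicit NaNs; timestamps are never dropped.
* **Median filter.**  Centered 30 s window on timestamps, shrinking at the
  record edges, NaNs excluded from each window and preserved in place.
* **Robust smoother.**  Minimizes ‖W½(y − z)‖² + s‖Dz‖² with D the
  second-difference operator under reflective (Neumann) boundaries, solved
  in the orthonormal DCT-II basis where the penalized system is diagonal.
  A best-fit line is removed first and restored after, so linear signals
  (the penalty null space) pass through exactly.  The smoothing parameter
  is selected by generalized cross-validation on a 61-point log grid over
  [1e-3, 1e6]; for records longer than 4096 samples the GCV sums run over
  a binned eigen-spectrum (exact below the 1024th coefficient) and the
  record is reflect-padded to a transform-friendly length, both purely
  numerical-efficiency choices.  Robust iterations use bisquare weights on
  MAD-standardized residuals and engage only when exceedances of the
  bisquare cutoff are clearly more frequent than Gaussian chance
  (fraction > 1e-4); convergence is declared at a relative change < 1e-3.
* **Admission window.**  Series truncated to 15 minutes; a patient is
  excluded when any numeric channel has under 5 minutes of valid samples
  (exactly 5 minutes passes).

## Beat detection and HRV conventions

The R-peak detector is a derivative-energy detector (band-pass 5–25 Hz,
differentiate, square, 150 ms moving integration, threshold at 20% of the
98th-percentile energy, refinement to the band-passed extremum, 250 ms
refractory).  The threshold is a percentile of the energy envelope, so
detection is invariant to positive amplitude scaling.  PPG pulses are
low-pass peaks with plateau-midpoint resolution for clipped pulses.
Artifact rejection removes intervals outside [300, 2000] ms or deviating
more than 20% from an 11-point running median; a series losing more than
half its intervals is flagged unreliable and its HRV features go missing.

HRV conventions (fixed so golden tests are meaningful): SD uses the n−1
denominator; IQR uses type-7 linear interpolation; pNN50 counts successive
differences strictly greater than 50 ms; Poincaré SD1/SD2 use population
variance; SampEn(m=2, r=0.2·SD) excludes self-matches; DFA α1 fits scales
4–16 and α2 scales 16–64.  Spectral bands are VLF 0.003–0.04, LF 0.04–0.15,
HF 0.15–0.4 Hz.  Welch runs on a 4 Hz cubic-spline tachogram (linear
detrend, Hann window, 50% overlap, segment length ≤ 1024 samples).  The
Lomb spectrum is evaluated on the irregular beat times with the classic
time-offset closed form, scaled so that on even sampling it equals the
classical periodogram density; the frequency grid uses the Rayleigh
resolution 1/T.  The AR spectrum uses Burg recursion with reflection
coefficients clipped to |k| ≤ 0.995 (noiseless sinusoids otherwise push
poles onto the unit circle), AIC order selection over 8–24, and band powers
integrated on a 16384-point grid fine enough to resolve near-unit-circle
poles.  ECG- and PPG-derived HRV features are kept as separate families;
whether the original system fused them is unknown.

## Models and tuning

ML-GCS is a 13-class classifier over the integer GCS values; ML-ISS is a
regressor on exact ISS.  Case weights are N/(K·count) on the coarsened
categories (GCS 3 bins, ISS 4 bins), making the weighted category masses
exactly equal.  Model kinds: XGBoost (`gbt`, NaNs routed natively), random
forest (`rf`, median-imputed), and elastic-net linear models (`linear`,
median-imputed and standardized; multinomial logistic for GCS).  Tuning is
randomized search with shuffled k-fold CV; the CV metric is case-weighted
micro one-vs-rest AUC (GCS) or negative weighted RMSE (ISS).  The
`TuningConfig` defaults carry the full protocol (50 draws × 10 replicates ×
5 folds); pipeline experiments default to a desk-scale budget (3 draws, 1
replicate, 5 folds) — on the synthetic cohort the search surface is flat
enough that larger budgets only reshuffle near-equivalent configurations.
The GCS point estimate is the argmax class with ties resolved to the lowest
(most severe) GCS, the triage-conservative choice.  Demographics are
excluded from the feature set by default so the models remain monitor-only.

Variable importance is permutation importance on held-out data (seeded
column permutations, mean score degradation, direction summarized by the
Spearman correlation of feature with prediction).  Exact tree-path
attribution methods can be attached externally; they are interpretive, not
part of the evaluated surface.

## Evaluation

Binary AUC is the tie-corrected Mann–Whitney statistic; a weighted variant
generalizes it to weighted concordant-pair counting.  Confidence intervals
default to DeLong's structural-components variance with a normal
approximation (a seeded stratified bootstrap is available).  Micro-averaged
multiclass AUC pools the one-hot expansion; macro averages over classes
present.  Mortality scoring direction: −RTS for RTS variants (lower RTS =
worse) and 1 − survival for TRISS variants.  Operating points maximize the
Youden index over observed cut-points with "positive if score ≥ threshold"
and ties resolved to the lowest threshold.

## Problem sizes and numerical choices

Experiments in the test suite and the acceptance script use cohorts of
3000 patients (2000 train / 1000 test at the chronological 2/3 split), the
size at which category counts are large enough for stable AUCs while a full
simulate-to-evaluate run stays comfortably within an interactive budget.
The qualitative score-substitution pattern is asserted over three seeds.
Waveform processing runs at the native 240 Hz over the full 15-minute
window (~216k samples per channel); cohorts stream patient by patient, so
memory stays flat.  Degenerate inputs follow one rule throughout: an
operation that cannot be computed returns explicitly flagged missing
values, and only label-missing or coverage-failing patients are excluded.

## Known limitations

* The TRISS coefficients are used as printed; no recalibration to the
  synthetic cohort, so absolute survival probabilities inherit TRISS's
  dated baseline.
* The shock-index dose uses SI = HR/SBP > 1 by default; the literal
  inverted ratio from the source material is available via
  `si_definition="sbp_over_hr"` but is the normal state and yields a
  near-zero dose.
* SampEn/DFA require ≥ 100 intervals and go missing on short or heavily
  rejected recordings rather than being computed on unreliable data.
* The linear model pair is substantially weaker than the tree models on
  this feature set (as expected for threshold-style physiologic effects);
  comparisons across model kinds share the same weighting and splits.
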