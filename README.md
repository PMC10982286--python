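# mltriss

Automated trauma-severity scoring from the first 15 minutes of continuous
vital signs.

In trauma resuscitation, the two labels that drive the standard severity
scores — the Glasgow Coma Scale (GCS) and the Injury Severity Score (ISS) —
are often delayed, subjective, or unavailable during triage.  `mltriss`
estimates both from features of continuous monitor data (ECG, PPG, numeric
vitals at 0.5 Hz), substitutes the estimates into the Revised Trauma Score
and the TRISS survival model, and evaluates how well the automated scores
discriminate in-hospital mortality.  Because suitable monitor registries
are not publicly available, the package ships a physiologically coupled
synthetic cohort generator, making every stage testable end to end.

## The scores

RTS is a weighted sum of coded GCS, systolic blood pressure and respiratory
rate points:

```
RTS = 0.9368·GCS_pts + 0.7326·SBP_pts + 0.2908·RR_pts        (range 0–7.8408)
```

TRISS maps RTS, ISS and an age ≥ 55 indicator through a mechanism-specific
logistic model to a probability of survival:

```
P(survive) = logistic(b0 + b1·RTS + b2·ISS + b3·1{age ≥ 55})
blunt:       (−0.4499, 0.8085, −0.0835, −1.743)
penetrating: (−2.5355, 0.9934, −0.0651, −1.136)
```

The ML-substituted variants are **ML-RTS** (ML-GCS in the RTS), **ML-TRISS**
(ML-ISS with the real GCS), and **ML-TRISS2** (both estimates).

The severity models consume ~100 monitor-only features per patient:
descriptive statistics of each numeric channel, time-normalized dose of
excursions beyond clinical thresholds (HR > 120 / < 60 bpm, SpO2 < 88%,
MBP < 50 mmHg, shock index > 1), and heart-rate-variability features in the
time domain (SDNN, RMSSD, pNN50, …), frequency domain (VLF/LF/HF band
powers by Welch, Lomb, and Burg autoregressive spectra), and nonlinear
domain (sample entropy, Poincaré SD1/SD2, detrended fluctuation analysis),
from both ECG- and PPG-derived beat series.

## Worked example

```python
from mltriss.pipeline import ExperimentConfig, run_experiment
from mltriss.synthetic_data import CohortConfig

cfg = ExperimentConfig(cohort=CohortConfig(n_patients=600, seed=7), seed=7)
result = run_experiment(cfg)

sub = result.report["subgroups"]["all"]
print("test patients:", sub["n"], " deaths:", sub["n_deaths"])
print("ML-GCS micro AUC:", round(sub["gcs_micro_auc"], 3))
print("ML-ISS Spearman :", round(sub["iss_spearman"], 3))
for name, block in sub["mortality"].items():
    print(f"{name:11s} AUROC {block['auroc']:.3f}")
```

Output from one run of this snippet:

```
test patients: 197  deaths: 7
ML-GCS micro AUC: 0.914
ML-ISS Spearman : 0.845
real_rts    AUROC 0.799
ml_rts      AUROC 0.737
real_triss  AUROC 0.891
ml_triss    AUROC 0.888
ml_triss2   AUROC 0.774
```

Reading it: the micro-averaged one-vs-rest AUC says the 13-class GCS model
ranks patients of each GCS value well despite heavy class imbalance; the
Spearman correlation says ML-ISS recovers the ISS ordering; and the AUROC
panel reproduces the qualitative substitution pattern — ML-TRISS tracks
TRISS closely (the ISS estimate is an adequate stand-in), while ML-RTS
loses ground against RTS because RTS leans almost entirely on exact GCS
points, which are harder to estimate.  At this toy size the AUROCs rest on
seven deaths; the test suite and acceptance script use 3000-patient
cohorts.

A command-line interface mirrors the stages
(`mltriss simulate|features|run-all`):

```bash
mltriss run-all --seed 11 --out results/run11
```

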