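"""End-to-end experiment orchestration.

simulate -> preprocess -> features -> train -> score -> evaluate, as one
reproducible, seeded experiment:

1. a synthetic cohort is streamed patient by patient; each patient's
   numeric vitals are range-filtered and median-filtered, waveforms are
   robust-smoothed, the 15-minute admission window is enforced, beats are
   detected and artifact-rejected, and the feature vector is assembled;
2. exclusion rules are applied (death within 15 min of admission, under 5
   minutes of usable vitals, missing GCS/ISS labels) with a rule-tagged
   exclusion ledger;
3. the cohort is split chronologically by admission order (earlier fraction
   trains, later tests — no test-period patient is seen during tuning);
4. ML-GCS and ML-ISS are trained with inverse-category-frequency weights;
5. the four score panels (real, ML-RTS, ML-TRISS, ML-TRISS2) are assembled
   per test patient using the measured SBP/RR medians for points coding;
6. mortality discrimination is evaluated per subgroup (all, polyTBI = head
   AIS >= 1, isoTBI = head AIS >= 1 and other AIS <= 1) with DeLong CIs and
   Youden operating metrics.  RTS variants score mortality by -RTS (lower
   RTS = worse); TRISS variants by mortality risk = 1 - survival.

The metric report is a plain JSON-serializable dict stamped with the config
hash and seed; identical config and seed reproduce it byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import trauma_scores
from .beat_detection import clean_intervals, detect_ppg_pulses, detect_r_peaks
from .categories import GCS_POINTS_CATEGORIES, ISS_CATEGORIES
from .evaluation import auc_ci, binary_auc, confusion, multiclass_auc, youden_metrics
from .feature_extraction import assemble_features
from .preprocessing import (
    DEFAULT_LIMITS,
    apply_admission_window,
    filter_physiologic_range,
    median_filter,
    robust_smooth,
)
from .severity_models import (
    GCS_CLASSES,
    TuningConfig,
    compute_case_weights,
    predict_severity,
    train_gcs_model,
    train_iss_model,
)
from .synthetic_data import CohortConfig, PatientCase, iter_cohort

log = logging.getLogger("mltriss.pipeline")

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "apply_exclusions",
    "extract_cohort_features",
]

SUBGROUPS = ("all", "polytbi", "isotbi")
VARIANTS = ("real_rts", "ml_rts", "real_triss", "ml_triss", "ml_triss2")


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one simulate-train-evaluate experiment."""

    cohort: CohortConfig = CohortConfig()
    train_fraction: float = 2.0 / 3.0
    model_kind: str = "gbt"
    tuning: TuningConfig = TuningConfig(n_draws=3, replicates=1, folds=5)
    seed: int = 0
    si_definition: str = "hr_over_sbp"
    smooth_waveforms: bool = True
    output_dir: Optional[str] = None

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")

    def config_hash(self) -> str:
        blob = json.dumps(_to_jsonable(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _process_patient(case, signals, cfg: ExperimentConfig) -> Optional[dict]:
    """Clean one patient's signals and return the feature row, or None if
    the admission-window coverage rule excludes the patient."""
    numeric = {}
    qc = {}
    for ch, s in signals.numeric.items():
        filt, n_removed = filter_physiologic_range(s, DEFAULT_LIMITS)
        numeric[ch] = median_filter(filt)
        qc[ch] = n_removed
    signals.numeric = numeric
    win = apply_admission_window(signals, cfg.cohort.window_minutes)
    if win.excluded:
        return None
    sig = win.signals

    ecg_rr = ppg_rr = None
    if sig.ecg is not None:
        ecg = robust_smooth(sig.ecg) if cfg.smooth_waveforms else sig.ecg
        det = detect_r_peaks(ecg)
        if det.intervals_ms.size:
            ecg_rr = clean_intervals(det)
    if sig.ppg is not None:
        ppg = robust_smooth(sig.ppg) if cfg.smooth_waveforms else sig.ppg
        det = detect_ppg_pulses(ppg)
        if det.intervals_ms.size:
            ppg_rr = clean_intervals(det)

    fv = assemble_features(
        sig.numeric, ecg_rr, ppg_rr, si_definition=cfg.si_definition
    )
    row = dict(fv.values)

    def _median(ch):
        if ch not in sig.numeric:
            return np.nan
        v = sig.numeric[ch].values
        v = v[np.isfinite(v)]
        return float(np.median(v)) if v.size else np.nan

    row["_sbp_median"] = _median("SBP")
    row["_rr_median"] = _median("RR")
    row["_coverage_minutes"] = win.coverage_minutes
    row["_qc_removed"] = int(sum(qc.values()))
    return row


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a cohort table into kept and excluded (with reasons).

    Rules, in order: died within 15 min of admission; under 5 minutes of
    usable continuous vitals; missing GCS, ISS, or mortality outcome.
    """
    reasons = pd.Series("", index=cohort.index, dtype=object)
    died = cohort["died_within_15min"].astype(bool)
    reasons[died] = "early_death"
    short = ~died & (cohort["coverage_minutes"] < 5.0)
    reasons[short] = "insufficient_vs"
    missing = (
        ~died
        & ~short
        & ~(
            cohort["gcs_available"].astype(bool)
            & cohort["iss_available"].astype(bool)
            & cohort["mortality"].notna()
        )
    )
    reasons[missing] = "missing_label"
    excluded = cohort[reasons != ""].copy()
    excluded["exclusion_reason"] = reasons[reasons != ""]
    kept = cohort[reasons == ""].copy()
    assert len(kept) + len(excluded) == len(cohort)
    return kept, excluded


def extract_cohort_features(cfg: ExperimentConfig) -> pd.DataFrame:
    """Stream the synthetic cohort through cleaning and feature extraction.

    Returns one row per generated patient: PatientCase fields, QC metadata,
    and the feature columns; patients failing the coverage rule carry NaN
    features and a coverage below 5 minutes.
    """
    rows = []
    for case, signals in iter_cohort(cfg.cohort):
        meta = asdict(case)
        meta.pop("recorded_minutes")
        feats = _process_patient(case, signals, cfg)
        if feats is None:
            meta["coverage_minutes"] = case.recorded_minutes
            rows.append(meta)
            continue
        meta["coverage_minutes"] = feats.pop("_coverage_minutes")
        meta["sbp_median"] = feats.pop("_sbp_median")
        meta["rr_median"] = feats.pop("_rr_median")
        meta["qc_removed"] = feats.pop("_qc_removed")
        meta.update(feats)
        rows.append(meta)
    df = pd.DataFrame(rows)
    log.info("cohort extracted: %d patients, %d columns", len(df), df.shape[1])
    return df


_META_COLS = {
    "id", "age", "sex", "mechanism", "gcs", "iss", "head_ais", "max_other_ais",
    "mortality", "latent_severity", "admission_order", "mortality_risk",
    "died_within_15min", "gcs_available", "iss_available",
    "coverage_minutes", "sbp_median", "rr_median", "qc_removed",
    "ml_gcs", "ml_iss",
}


def _feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in _META_COLS]


@dataclass
class ExperimentResult:
    report: dict
    cohort: pd.DataFrame
    test: pd.DataFrame
    gcs_model: object
    iss_model: object
    exclusions: pd.DataFrame


def _subgroup_mask(df: pd.DataFrame, name: str) -> np.ndarray:
    if name == "all":
        return np.ones(len(df), dtype=bool)
    poly = df["head_ais"].to_numpy() >= 1
    if name == "polytbi":
        return poly
    if name == "isotbi":
        return poly & (df["max_other_ais"].to_numpy() <= 1)
    raise ValueError(f"unknown subgroup {name!r}")


def _score_block(scores: np.ndarray, deaths: np.ndarray, seed: int) -> dict:
    out = {"auroc": binary_auc(scores, deaths)}
    lo, hi = auc_ci(scores, deaths, method="delong")
    out["auroc_ci"] = [lo, hi]
    y = youden_metrics(scores, deaths)
    out["youden"] = {
        "threshold": y.threshold, "tpr": y.tpr, "tnr": y.tnr, "ppv": y.ppv,
        "npv": y.npv, "accuracy": y.accuracy, "f1": y.f1,
    }
    return out


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute the full pipeline and return metrics plus fitted models."""
    cohort = extract_cohort_features(config)
    kept, excluded = apply_exclusions(cohort)
    log.info("exclusions: %d kept, %d excluded", len(kept), len(excluded))

    # isoTBI is a subset of polyTBI by construction; assert on every cohort
    iso = _subgroup_mask(kept, "isotbi")
    poly = _subgroup_mask(kept, "polytbi")
    assert not np.any(iso & ~poly)

    kept = kept.sort_values("admission_order").reset_index(drop=True)
    n_train = int(round(config.train_fraction * len(kept)))
    train, test = kept.iloc[:n_train], kept.iloc[n_train:].reset_index(drop=True)
    feat_cols = _feature_columns(kept)

    tuning = dataclasses.replace(
        config.tuning, model_kind=config.model_kind, seed=config.seed
    )
    w_gcs = compute_case_weights(train["gcs"].to_numpy(), "gcs")
    w_iss = compute_case_weights(train["iss"].to_numpy(), "iss")
    gcs_model = train_gcs_model(train[feat_cols], train["gcs"].to_numpy(), w_gcs, tuning)
    iss_model = train_iss_model(train[feat_cols], train["iss"].to_numpy(), w_iss, tuning)

    estimates = predict_severity(gcs_model, iss_model, test[feat_cols])
    ml_gcs = np.array([e.gcs_point_estimate for e in estimates])
    ml_iss = np.array([e.iss_estimate for e in estimates])
    probs = np.vstack([e.gcs_class_probs for e in estimates])

    # TRISS evaluation subset: blunt/penetrating only (always true here, but
    # the rule is applied for registry-shaped data)
    test = test.assign(ml_gcs=ml_gcs, ml_iss=ml_iss)
    triss_ok = test["mechanism"].isin(["blunt", "penetrating"]).to_numpy()

    panels = {v: np.full(len(test), np.nan) for v in VARIANTS}
    for i, row in test.iterrows():
        if not triss_ok[i] or not np.isfinite(row["sbp_median"]):
            continue
        p = trauma_scores.assemble_panels(
            gcs=int(row["gcs"]), iss=float(row["iss"]), age=row["age"],
            mechanism=row["mechanism"], measured_sbp=row["sbp_median"],
            measured_rr=row["rr_median"], ml_gcs=int(row["ml_gcs"]),
            ml_iss=float(row["ml_iss"]),
        )
        panels["real_rts"][i] = p["real"].rts
        panels["ml_rts"][i] = p["ml_rts"].rts
        panels["real_triss"][i] = p["real"].mortality_risk
        panels["ml_triss"][i] = p["ml_triss"].mortality_risk
        panels["ml_triss2"][i] = p["ml_triss2"].mortality_risk

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_generated": len(cohort),
        "n_excluded": len(excluded),
        "exclusion_reasons": _to_jsonable(
            excluded["exclusion_reason"].value_counts().to_dict()
            if len(excluded)
            else {}
        ),
        "n_train": len(train),
        "n_test": len(test),
        "gcs_cv_score": gcs_model.cv_score,
        "iss_cv_score": iss_model.cv_score,
        "subgroups": {},
    }

    for sg in SUBGROUPS:
        m = _subgroup_mask(test, sg)
        deaths = test["mortality"].to_numpy(dtype=bool)[m]
        block = {"n": int(m.sum()), "n_deaths": int(deaths.sum())}
        if m.sum() >= 10:
            mc = multiclass_auc(probs[m], test["gcs"].to_numpy()[m], GCS_CLASSES)
            block["gcs_macro_auc"] = mc.macro
            block["gcs_micro_auc"] = mc.micro
            block["gcs_per_class_auc"] = {
                str(k): v for k, v in sorted(mc.per_class.items())
            }
            block["iss_spearman"] = float(
                spearmanr(test["ml_iss"].to_numpy()[m], test["iss"].to_numpy()[m]).statistic
            )
            cm, tpr = confusion(
                test["ml_iss"].round().clip(1, 75).astype(int).to_numpy()[m],
                test["iss"].to_numpy()[m],
                ISS_CATEGORIES,
            )
            block["iss_confusion"] = _to_jsonable(cm.to_numpy())
            block["iss_category_tpr"] = _to_jsonable(tpr.to_dict())
            gm, gtpr = confusion(
                test["ml_gcs"].to_numpy()[m], test["gcs"].to_numpy()[m],
                GCS_POINTS_CATEGORIES,
            )
            block["gcs_points_confusion"] = _to_jsonable(gm.to_numpy())
            block["gcs_points_tpr"] = _to_jsonable(gtpr.to_dict())
        block["mortality"] = {}
        for v in VARIANTS:
            sc = panels[v][m]
            ok = np.isfinite(sc)
            if deaths[ok].sum() < 2 or (~deaths[ok]).sum() < 2:
                continue
            direction = -1.0 if v.endswith("rts") else 1.0
            block["mortality"][v] = _score_block(
                direction * sc[ok], deaths[ok], config.seed
            )
        report["subgroups"][sg] = block

    report = _to_jsonable(report)
    result = ExperimentResult(report, cohort, test, gcs_model, iss_model, excluded)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
        cohort.to_csv(out / "cohort.csv", index=False)
        excluded.to_csv(out / "exclusions.csv", index=False)
    return result
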