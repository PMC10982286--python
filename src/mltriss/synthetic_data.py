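"""Synthetic trauma cohort generator with physiologically coupled signals.

Every patient carries a scalar latent severity ``s ~ N(0, 1)``.  Two noisy
copies of it drive the clinical labels:

* the GCS latent sets the mild/moderate/severe TBI category by fixed normal
  thresholds reproducing the configured class imbalance (default 88.5 / 3.7 /
  7.8%, the testing-cohort mix), with a uniform integer inside the category;
* the ISS latent maps through a log-normal transform calibrated so the
  mild/moderate/severe/profound ISS bins appear at roughly 55 / 25 / 11 / 9%.

Physiology couples to the same latents: heart rate rises and SDNN / HF power
fall linearly in the GCS latent (autonomic dysfunction tracks neuro status),
while transient hypotensive episodes and desaturation deepen with the ISS
latent (hemorrhagic compromise tracks anatomic injury).  Mortality is drawn
as Bernoulli(1 - TRISS survival) from the true GCS/ISS/age/mechanism, so the
cohort's mortality process is exactly the scoring model under evaluation.

Signals per patient: 0.5 Hz numeric channels (HR, SpO2, SBP, DBP, MBP, RR)
and 240 Hz ECG/PPG waveforms over a 15-minute window.  Waveforms are
template-based (Gaussian QRS-like bump; raised-cosine pulse): sufficient for
beat detection, with no morphology claims.

All randomness flows from a single cohort seed through per-patient
``SeedSequence`` children, so cohorts are bit-identical across runs and the
generator can stream (``iter_cohort``) without holding every waveform in
memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterator, Optional

import numpy as np
from scipy.stats import norm

from .preprocessing import NumericVitalSeries, PatientSignals, Waveform
from .beat_detection import BeatIntervalSeries
from .trauma_scores import rts_from_values, triss_survival

__all__ = [
    "CohortConfig",
    "PatientCase",
    "RrModulation",
    "ConfigurationError",
    "generate_cohort",
    "iter_cohort",
    "generate_rr_series",
    "generate_ecg_from_rr",
    "generate_ppg_from_rr",
    "write_cohort_csv",
    "write_numeric_csv",
    "write_waveform",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class RrModulation:
    """Spectral profile of RR-interval modulation.

    Variance fractions are allocated to a low-frequency tone (0.04-0.15 Hz
    band), a high-frequency tone (0.15-0.4 Hz, respiratory), and white
    beat-to-beat noise; they must sum to 1.
    """

    lf_freq: float = 0.095
    hf_freq: float = 0.275
    lf_frac: float = 0.45
    hf_frac: float = 0.35
    noise_frac: float = 0.20

    def __post_init__(self):
        total = self.lf_frac + self.hf_frac + self.noise_frac
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("modulation variance fractions must sum to 1")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 100
    seed: int = 0
    gcs_class_probs: tuple[float, float, float] = (0.885, 0.037, 0.078)
    severity_coupling: float = 1.0
    noise_sd: float = 0.05  # waveform additive noise, relative to unit QRS
    window_minutes: float = 15.0
    numeric_hz: float = 0.5
    wave_hz: float = 240.0
    p_blunt: float = 0.60
    p_female: float = 0.29
    p_short_recording: float = 0.01
    p_missing_label: float = 0.005
    p_early_death: float = 0.003

    def __post_init__(self):
        p = np.asarray(self.gcs_class_probs, dtype=float)
        if p.size != 3 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                "gcs_class_probs must be 3 non-negative numbers summing to 1"
            )
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if self.window_minutes <= 0 or self.numeric_hz <= 0 or self.wave_hz <= 0:
            raise ConfigurationError("rates and durations must be strictly positive")
        if self.severity_coupling < 0:
            raise ConfigurationError("severity_coupling must be >= 0")


@dataclass
class PatientCase:
    """Demographics, ground-truth labels, and outcome for one patient."""

    id: str
    age: float
    sex: str
    mechanism: str
    gcs: int
    iss: int
    head_ais: int
    max_other_ais: int
    mortality: bool
    latent_severity: float
    admission_order: int = 0
    mortality_risk: float = 0.0  # generator-only: 1 - TRISS survival
    recorded_minutes: float = 15.0
    died_within_15min: bool = False
    gcs_available: bool = True
    iss_available: bool = True

    def __post_init__(self):
        if not 3 <= self.gcs <= 15:
            raise ValueError("gcs must be in [3, 15]")
        if not 1 <= self.iss <= 75:
            raise ValueError("iss must be in [1, 75]")
        if not 18 <= self.age <= 90:
            raise ValueError("age must be in [18, 90]")


# ISS log-normal calibration: ISS = round(exp(mu + sigma * h)), h ~ N(0,1),
# matching the testing-cohort bin fractions (~55/25/11/9%).
_ISS_MU = 2.04
_ISS_SIGMA = 0.84

# GCS category bins (category index 0=mild, 1=moderate, 2=severe) with
# within-category integer masses shaped like real admission cohorts
# (median 15 with IQR [14, 15]; GCS 3 dominates the severe bin)
_GCS_BINS = ((13, 15), (9, 12), (3, 8))
_GCS_WITHIN = (
    ((13, 14, 15), (0.10, 0.15, 0.75)),
    ((9, 10, 11, 12), (0.25, 0.25, 0.25, 0.25)),
    ((3, 4, 5, 6, 7, 8), (0.45, 0.10, 0.10, 0.12, 0.11, 0.12)),
)

# ISS latent mixes the shared severity with its own noise; the mixing weight
# yields a GCS-ISS association (|r| ~ 0.4) typical of trauma registries
_ISS_MIX = 1.5 / np.sqrt(1.0 + 1.5**2)


def _softplus(x, beta=1.5):
    return np.log1p(np.exp(beta * np.minimum(x, 30.0))) / beta


def generate_rr_series(
    mean_rr_ms: float,
    sdnn_target_ms: float,
    lf_hf_profile: RrModulation = RrModulation(),
    duration_s: float = 900.0,
    seed: int | np.random.SeedSequence = 0,
) -> BeatIntervalSeries:
    """Ground-truth RR series: sinusoidal LF + HF modulation plus white noise.

    The realized mean is within 2% of ``mean_rr_ms`` (modulation is
    zero-mean) and the realized SD approaches ``sdnn_target_ms``.  With a
    zero target the series is exactly constant.
    """
    if mean_rr_ms <= 0:
        raise ValueError("mean_rr_ms must be positive")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n = int(np.ceil(duration_s * 1000.0 / mean_rr_ms)) + 2
    t_nom = np.arange(n) * mean_rr_ms / 1000.0  # nominal beat times, s
    p = lf_hf_profile
    if sdnn_target_ms > 0:
        a_lf = sdnn_target_ms * np.sqrt(2.0 * p.lf_frac)
        a_hf = sdnn_target_ms * np.sqrt(2.0 * p.hf_frac)
        sd_w = sdnn_target_ms * np.sqrt(p.noise_frac)
        phi1, phi2 = rng.uniform(0, 2 * np.pi, size=2)
        mod = a_lf * np.sin(2 * np.pi * p.lf_freq * t_nom + phi1) + a_hf * np.sin(
            2 * np.pi * p.hf_freq * t_nom + phi2
        )
        w = rng.normal(0.0, sd_w, size=n) if sd_w > 0 else 0.0
        intervals = mean_rr_ms + mod + w
    else:
        intervals = np.full(n, mean_rr_ms)
    intervals = np.clip(intervals, 280.0, 2200.0)
    beat_times = np.concatenate([[0.0], np.cumsum(intervals) / 1000.0])
    keep = beat_times <= duration_s
    beat_times = beat_times[keep]
    # carry the exact interval values (a cumsum/diff round trip would add
    # float jitter to nominally constant series)
    return BeatIntervalSeries(
        beat_times, intervals[: beat_times.size - 1], source="RR"
    )


_QRS_SIGMA_S = 0.012  # Gaussian QRS-like bump width


def generate_ecg_from_rr(
    rr: BeatIntervalSeries,
    wave_hz: float = 240.0,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> Waveform:
    """Render an ECG-like waveform with one Gaussian bump per beat."""
    if rr.n_beats == 0:
        raise ValueError("rr series is empty")
    if wave_hz < 50:
        raise ValueError("wave_hz too low to resolve peaks (< 50 Hz)")
    rng = np.random.default_rng(seed)
    duration = rr.beat_times[-1] + 0.5
    n = int(np.ceil(duration * wave_hz))
    half = int(np.ceil(4 * _QRS_SIGMA_S * wave_hz))
    kernel_t = np.arange(-half, half + 1) / wave_hz
    kernel = np.exp(-0.5 * (kernel_t / _QRS_SIGMA_S) ** 2)
    # on-grid peak centers so detection can be sample-exact
    centers = np.round(rr.beat_times * wave_hz).astype(np.int64)
    y = _scatter_kernel(centers, kernel, half, n)
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=n)
    return Waveform("ECG", wave_hz, y, t0=0.0)


def _scatter_kernel(centers: np.ndarray, kernel: np.ndarray, half: int, n: int) -> np.ndarray:
    idx = centers[:, None] + np.arange(-half, half + 1)[None, :]
    w = np.broadcast_to(kernel, idx.shape)
    mask = (idx >= 0) & (idx < n)
    return np.bincount(idx[mask], weights=w[mask], minlength=n).astype(float)


_PULSE_WIDTH_S = 0.30  # raised-cosine pulse duration
_PULSE_DELAY_S = 0.20  # pulse-arrival delay after the R peak


def generate_ppg_from_rr(
    rr: BeatIntervalSeries,
    wave_hz: float = 240.0,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> Waveform:
    """Render a PPG-like waveform: one raised-cosine pulse per beat.

    Each pulse peaks a fixed delay after its beat, so inter-peak intervals
    equal the RR intervals exactly.
    """
    if rr.n_beats == 0:
        raise ValueError("rr series is empty")
    if wave_hz < 50:
        raise ValueError("wave_hz too low to resolve peaks (< 50 Hz)")
    rng = np.random.default_rng(seed)
    duration = rr.beat_times[-1] + 0.8
    n = int(np.ceil(duration * wave_hz))
    half = int(np.ceil(_PULSE_WIDTH_S / 2 * wave_hz))
    tt = np.arange(-half, half + 1) / wave_hz
    kernel = 0.5 * (1.0 + np.cos(2 * np.pi * tt / _PULSE_WIDTH_S))
    centers = np.round((rr.beat_times + _PULSE_DELAY_S) * wave_hz).astype(np.int64)
    y = _scatter_kernel(centers, kernel, half, n)
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=n)
    return Waveform("PPG", wave_hz, y, t0=0.0)


def _episode_profile(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Smooth transient episode shape (Gaussian in time), peak 1."""
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _draw_case(cfg: CohortConfig, idx: int, rng: np.random.Generator) -> dict:
    """Draw demographics, latents, labels and physiologic setpoints."""
    c = cfg.severity_coupling
    s = rng.normal()
    age = float(np.clip(rng.normal(43.0, 19.0), 18.0, 90.0))
    sex = "F" if rng.random() < cfg.p_female else "M"
    mechanism = "blunt" if rng.random() < cfg.p_blunt else "penetrating"

    mix = c / np.sqrt(1.0 + c * c) if c > 0 else 0.0
    res = np.sqrt(1.0 - mix * mix)

    # GCS: category by thresholds on a standard-normal latent
    g_lat = mix * s + res * rng.normal()
    p = cfg.gcs_class_probs
    thr1, thr2 = norm.ppf(p[0]), norm.ppf(p[0] + p[1])
    cat = 0 if g_lat < thr1 else (1 if g_lat < thr2 else 2)
    values, probs = _GCS_WITHIN[cat]
    gcs = int(rng.choice(values, p=probs))

    # ISS: log-normal transform of its own latent, floored by the anatomic
    # constraint ISS >= max(AIS)^2 (ISS sums squares of the top-3 AIS codes)
    h_mix = _ISS_MIX if c > 0 else 0.0
    h_lat = h_mix * s + np.sqrt(1.0 - h_mix**2) * rng.normal()
    iss_raw = int(np.clip(np.round(np.exp(_ISS_MU + _ISS_SIGMA * h_lat)), 1, 75))

    # AIS consistent with the polyTBI / isoTBI definitions
    head_lat = 0.8 * g_lat + 0.6 * rng.normal()
    if head_lat < norm.ppf(0.45):
        head_ais = 0
    else:
        head_ais = int(np.clip(1 + np.round(1.3 * _softplus(head_lat)), 1, 6))
    other_lat = 0.8 * h_lat + 0.6 * rng.normal()
    if other_lat < norm.ppf(0.35):
        max_other_ais = 0
    else:
        max_other_ais = int(np.clip(np.round(0.5 + 1.5 * _softplus(other_lat)), 1, 6))
    iss = int(np.clip(max(iss_raw, head_ais**2, max_other_ais**2), 1, 75))

    # physiologic setpoints: autonomic dysfunction (tachycardia, HRV
    # depression) tracks the latent severity s; the baseline pressures,
    # hypotensive episodes and desaturation additionally carry a hemorrhagic
    # component shared with the ISS latent.  The GCS/ISS labels are noisy
    # measurements of s, so vital-sign models recover them only up to that
    # label noise.
    d_lat = 0.5 * s + 0.5 * h_lat  # hemorrhage driver, partly ISS-specific
    hr0 = float(np.clip(75.0 + 9.0 * c * s + rng.normal(0, 6.0), 45.0, 180.0))
    sbp0 = float(
        np.clip(
            126.0 - 6.0 * c * s - 6.0 * c * _softplus(d_lat - 0.2) + rng.normal(0, 6.0),
            60.0,
            200.0,
        )
    )
    dbp0 = float(np.clip(0.62 * sbp0 + rng.normal(0, 4.0), 30.0, 140.0))
    rr0 = float(np.clip(16.0 + 3.0 * c * s + rng.normal(0, 2.0), 6.0, 45.0))
    spo2_0 = float(np.clip(98.0 - 0.6 * c * _softplus(s) + rng.normal(0, 0.5), 80.0, 100.0))
    sdnn0 = float(np.clip(42.0 - 11.0 * c * s + rng.normal(0, 6.0), 3.0, 90.0))
    hf_shift = float(np.clip(0.35 - 0.10 * c * s, 0.05, 0.75))

    # nadir depth grows supra-linearly with the hemorrhage latent: profound
    # injury produces frank hypotension (MBP nadirs in the 40-60 range),
    # moderate injury only modest dips
    dip_depth = float(9.0 * c * _softplus(d_lat - 0.2) ** 1.6 + rng.normal(0, 1.5))
    dip_depth = max(0.0, dip_depth)
    # desaturation tracks chest injury, only one component of overall
    # anatomic severity — weakly coupled to the ISS latent
    chest_lat = 0.4 * h_lat + 0.9 * rng.normal()
    desat_depth = float(max(0.0, 5.0 * c * _softplus(chest_lat - 1.0) + rng.normal(0, 0.5)))

    # outcome from the true scores; mechanism-specific TRISS
    rts_true = float(rts_from_values(gcs, sbp0, rr0))
    surv = float(triss_survival(rts_true, float(iss), age, mechanism))
    risk = 1.0 - surv
    mortality = bool(rng.random() < risk)

    recorded = cfg.window_minutes
    if rng.random() < cfg.p_short_recording:
        recorded = float(rng.uniform(1.0, 5.0))
    died_early = bool(rng.random() < cfg.p_early_death)
    gcs_avail = rng.random() >= cfg.p_missing_label
    iss_avail = rng.random() >= cfg.p_missing_label

    return dict(
        id=f"P{idx:06d}",
        age=age,
        sex=sex,
        mechanism=mechanism,
        gcs=gcs,
        iss=iss,
        head_ais=head_ais,
        max_other_ais=max_other_ais,
        mortality=mortality,
        latent_severity=float(s),
        admission_order=idx,
        mortality_risk=risk,
        recorded_minutes=recorded,
        died_within_15min=died_early,
        gcs_available=bool(gcs_avail),
        iss_available=bool(iss_avail),
        # setpoints passed on to the signal stage
        _setpoints=dict(
            hr0=hr0,
            sbp0=sbp0,
            dbp0=dbp0,
            rr0=rr0,
            spo2_0=spo2_0,
            sdnn0=sdnn0,
            hf_shift=hf_shift,
            dip_depth=dip_depth,
            desat_depth=desat_depth,
        ),
    )


def _make_signals(
    cfg: CohortConfig,
    sp: dict,
    recorded_minutes: float,
    rng: np.random.Generator,
    include_waveforms: bool = True,
) -> PatientSignals:
    dur = recorded_minutes * 60.0
    nt = int(np.floor(dur * cfg.numeric_hz))
    t = (np.arange(nt) + 1.0) / cfg.numeric_hz  # 2 s spacing, strictly increasing
    c = cfg.severity_coupling

    mod = RrModulation(
        lf_frac=0.80 - sp["hf_shift"],
        hf_frac=sp["hf_shift"],
        noise_frac=0.20,
    )
    rr = generate_rr_series(
        mean_rr_ms=60000.0 / sp["hr0"],
        sdnn_target_ms=sp["sdnn0"],
        lf_hf_profile=mod,
        duration_s=dur,
        seed=rng.integers(0, 2**31 - 1),
    )

    # hypotensive episodes shared across pressure channels and SpO2: the
    # nadir depth tracks severity while count and duration vary freely, so
    # window SDs carry shape randomness the minimum does not
    n_ep = 1 + rng.poisson(0.6)
    dip = np.zeros(nt)
    for _ in range(n_ep):
        center = rng.uniform(0.15 * dur, 0.85 * dur)
        width = rng.uniform(25.0, 140.0)
        rel_depth = rng.uniform(0.6, 1.0)
        dip = np.maximum(dip, rel_depth * _episode_profile(t, center, width))
    if dip.max() > 0:
        dip /= dip.max()  # the deepest episode reaches the full depth

    # severity-independent slow blood-pressure wander
    drift_amp = rng.uniform(0.0, 4.0)
    drift = drift_amp * np.sin(
        2 * np.pi * t / rng.uniform(180.0, 480.0) + rng.uniform(0, 2 * np.pi)
    )

    # HR numeric channel derives from the RR series (monitor-style)
    if rr.intervals_ms.size > 0:
        hr_inst = 60000.0 / rr.intervals_ms
        hr_num = np.interp(t, rr.interval_times, hr_inst)
    else:
        hr_num = np.full(nt, sp["hr0"])
    hr_num = hr_num + 4.0 * c * sp["dip_depth"] / 16.0 * dip + rng.normal(0, 1.5, nt)

    # Pressures interpolate between the patient's baseline and an ABSOLUTE
    # nadir level set by the hemorrhage magnitude: decompensation drives
    # perfusion pressure toward a severity-determined floor regardless of
    # the pre-injury baseline.  Displayed SBP/DBP numerics fluctuate beat
    # to beat; the monitor's mean pressure (computed from the waveform) is
    # the steadiest channel.
    mbp0 = (sp["sbp0"] + 2.0 * sp["dbp0"]) / 3.0
    sbp_nadir = 126.0 - 1.25 * sp["dip_depth"]
    dbp_nadir = 78.0 - 0.9 * sp["dip_depth"]
    mbp_nadir = 93.0 - sp["dip_depth"]
    sbp = np.clip(
        sp["sbp0"] * (1 - dip) + np.minimum(sbp_nadir, sp["sbp0"]) * dip
        + drift + rng.normal(0, 4.0, nt),
        30.0, None,
    )
    dbp = np.clip(
        sp["dbp0"] * (1 - dip) + np.minimum(dbp_nadir, sp["dbp0"]) * dip
        + 0.8 * drift + rng.normal(0, 3.0, nt),
        20.0, None,
    )
    mbp = np.clip(
        mbp0 * (1 - dip) + np.minimum(mbp_nadir, mbp0) * dip
        + 0.87 * drift + rng.normal(0, 0.8, nt),
        25.0, None,
    )
    # pulse oximetry is artifact-prone during resuscitation
    spo2 = np.clip(
        sp["spo2_0"] - sp["desat_depth"] * dip + rng.normal(0, 1.2, nt), 50.0, 100.0
    )
    rrate = np.clip(sp["rr0"] + rng.normal(0, 1.0, nt), 0.0, 60.0)

    numeric = {
        "HR": NumericVitalSeries("HR", t, hr_num),
        "SBP": NumericVitalSeries("SBP", t, sbp),
        "DBP": NumericVitalSeries("DBP", t, dbp),
        "MBP": NumericVitalSeries("MBP", t, mbp),
        "SpO2": NumericVitalSeries("SpO2", t, spo2),
        "RR": NumericVitalSeries("RR", t, rrate),
    }

    ecg = ppg = None
    if include_waveforms:
        ecg = generate_ecg_from_rr(
            rr, cfg.wave_hz, cfg.noise_sd, seed=rng.integers(0, 2**31 - 1)
        )
        ppg = generate_ppg_from_rr(
            rr, cfg.wave_hz, 0.6 * cfg.noise_sd, seed=rng.integers(0, 2**31 - 1)
        )
    return PatientSignals(numeric=numeric, ecg=ecg, ppg=ppg, rr_true=rr)


def iter_cohort(
    config: CohortConfig, include_waveforms: bool = True
) -> Iterator[tuple[PatientCase, PatientSignals]]:
    """Stream (PatientCase, PatientSignals) pairs; deterministic in the seed."""
    children = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        d = _draw_case(config, i, rng)
        sp = d.pop("_setpoints")
        case = PatientCase(**d)
        signals = _make_signals(
            config, sp, case.recorded_minutes, rng, include_waveforms
        )
        yield case, signals


def generate_cohort(
    config: CohortConfig, include_waveforms: bool = True
) -> list[tuple[PatientCase, PatientSignals]]:
    """Materialize a full cohort (use ``iter_cohort`` for large n)."""
    return list(iter_cohort(config, include_waveforms))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_cohort_csv(cases: list[PatientCase], path) -> None:
    import pandas as pd

    rows = []
    for c in cases:
        d = asdict(c)
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_numeric_csv(signals: PatientSignals, path) -> None:
    """Long-format CSV: time_s, channel, value."""
    import pandas as pd

    frames = []
    for ch, s in signals.numeric.items():
        frames.append(
            pd.DataFrame({"time_s": s.times, "channel": ch, "value": s.values})
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_waveform(wave: Waveform, path_prefix: str) -> None:
    """Flat binary samples (.npy) plus a JSON header sidecar."""
    np.save(f"{path_prefix}.npy", np.asarray(wave.samples, dtype=np.float32))
    header = {"channel": wave.channel, "rate": wave.rate, "t0": wave.t0,
              "n_samples": int(np.asarray(wave.samples).size)}
    with open(f"{path_prefix}.json", "w") as fh:
        json.dump(header, fh, indent=1)
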