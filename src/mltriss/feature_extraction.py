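"""Feature extraction from cleaned vitals and inter-beat interval series.

Families, mirroring the early-triage feature set:

* descriptive statistics (mean, SD, median, IQR, min, max) of each numeric
  channel over the admission window;
* dose features: time-normalized trapezoidal area of a vital sign beyond a
  clinical threshold (HR > 120 or < 60 bpm, SpO2 < 88%, MBP < 50 mmHg,
  shock index > 1).  Crossing points of piecewise-linear signals are
  inserted analytically, so the dose is exact for piecewise-linear inputs
  and invariant to grid refinement;
* shock index series SI = HR/SBP on the common time grid (the conventional
  ratio; a config switch provides the inverted SBP/HR variant);
* HRV time domain: mean NN, SDNN, RMSSD, NN50, pNN50, CV;
* HRV frequency domain in VLF (0.003-0.04), LF (0.04-0.15) and HF
  (0.15-0.4 Hz) bands, by three methods: Welch on a 4 Hz cubic-interpolated
  tachogram, Lomb least-squares spectrum on the irregular beat times, and a
  Burg autoregressive spectrum with AIC order selection (orders 8-24);
* HRV nonlinear: sample entropy (m=2, r=0.2*SD), Poincare SD1/SD2, and
  detrended fluctuation analysis slopes alpha1 (scales 4-16) and alpha2
  (16-64).

Conventions fixed for reproducibility: SD uses the n-1 denominator; IQR uses
linear (type-7) quantile interpolation; pNN50 counts successive differences
strictly greater than 50 ms; Poincare descriptors use population variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as ssig
from scipy.interpolate import CubicSpline

from .beat_detection import BeatIntervalSeries
from .preprocessing import NumericVitalSeries

__all__ = [
    "FeatureVector",
    "DoseSpec",
    "SpectralBands",
    "STANDARD_DOSES",
    "descriptive_stats",
    "dose",
    "shock_index_series",
    "hrv_time_domain",
    "hrv_frequency",
    "hrv_nonlinear",
    "assemble_features",
    "feature_names",
]


@dataclass
class FeatureVector:
    """Named feature map with explicit missingness and provenance."""

    values: dict[str, float] = field(default_factory=dict)
    missing: set[str] = field(default_factory=set)
    provenance: dict[str, str] = field(default_factory=dict)

    def set(self, name: str, value: float, source: str = "") -> None:
        if name in self.values:
            raise ValueError(f"duplicate feature name {name!r}")
        if value is None or not np.isfinite(value):
            self.values[name] = np.nan
            self.missing.add(name)
        else:
            self.values[name] = float(value)
        if source:
            self.provenance[name] = source

    def set_missing(self, name: str, source: str = "") -> None:
        self.set(name, np.nan, source)

    def update(self, other: "FeatureVector") -> "FeatureVector":
        for k, v in other.values.items():
            self.set(k, v, other.provenance.get(k, ""))
        self.missing |= other.missing
        return self

    def names(self) -> list[str]:
        return list(self.values)


@dataclass(frozen=True)
class DoseSpec:
    channel: str
    threshold: float
    direction: str  # "above" | "below"

    def __post_init__(self):
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.direction not in ("above", "below"):
            raise ValueError("direction must be 'above' or 'below'")


#: The stated clinical dose thresholds; the SI dose is added on the derived
#: shock-index series with threshold 1 (direction above).
STANDARD_DOSES = (
    DoseSpec("HR", 120.0, "above"),
    DoseSpec("HR", 60.0, "below"),
    DoseSpec("SpO2", 88.0, "below"),
    DoseSpec("MBP", 50.0, "below"),
)


@dataclass(frozen=True)
class SpectralBands:
    vlf: tuple[float, float] = (0.003, 0.04)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.40)

    def __post_init__(self):
        for lo, hi in (self.vlf, self.lf, self.hf):
            if hi <= lo:
                raise ValueError("band edges must be increasing")
        if self.vlf[1] > self.lf[0] or self.lf[1] > self.hf[0]:
            raise ValueError("bands must be disjoint and increasing")


def descriptive_stats(series: NumericVitalSeries, prefix: Optional[str] = None) -> FeatureVector:
    """Mean, SD (n-1), median, IQR (type-7), min, max of a numeric channel."""
    pre = (prefix or series.channel).lower()
    fv = FeatureVector()
    v = series.values[np.isfinite(series.values)]
    names = ("mean", "sd", "median", "iqr", "min", "max")
    if v.size < 2:
        for n in names:
            fv.set_missing(f"{pre}_{n}", series.channel)
        return fv
    q75, q25 = np.percentile(v, [75, 25])
    vals = (v.mean(), v.std(ddof=1), np.median(v), q75 - q25, v.min(), v.max())
    for n, x in zip(names, vals):
        fv.set(f"{pre}_{n}", x, series.channel)
    return fv


def dose(series: NumericVitalSeries, spec: DoseSpec) -> float:
    """Time-normalized integrated excursion beyond a threshold.

    Trapezoidal integral of max(0, value - threshold) (direction "above";
    mirrored for "below") divided by the observed valid duration.  Crossing
    points are inserted analytically, making the integral exact for
    piecewise-linear signals.  Returns NaN on a degenerate time span.
    """
    mask = np.isfinite(series.values)
    t, v = series.times[mask], series.values[mask]
    if t.size < 2 or t[-1] - t[0] <= 0:
        return np.nan
    e = v - spec.threshold
    if spec.direction == "below":
        e = -e
    # insert zero crossings between samples of opposite sign
    sgn = np.sign(e)
    cross = np.nonzero(sgn[:-1] * sgn[1:] < 0)[0]
    if cross.size:
        tc = t[cross] - e[cross] * (t[cross + 1] - t[cross]) / (e[cross + 1] - e[cross])
        t = np.insert(t, cross + 1, tc)
        e = np.insert(e, cross + 1, 0.0)
    excess = np.maximum(e, 0.0)
    area = np.trapezoid(excess, t)
    return float(area / (t[-1] - t[0]))


def shock_index_series(
    sbp: NumericVitalSeries,
    hr: NumericVitalSeries,
    si_definition: str = "hr_over_sbp",
) -> NumericVitalSeries:
    """Shock index on the common time grid.

    The conventional definition HR/SBP is the default; ``"sbp_over_hr"``
    computes the inverted printed ratio.  Missing or zero-denominator
    samples stay missing (no interpolation).
    """
    if si_definition not in ("hr_over_sbp", "sbp_over_hr"):
        raise ValueError(f"unknown si_definition {si_definition!r}")
    tt, ia, ib = np.intersect1d(hr.times, sbp.times, return_indices=True)
    if tt.size == 0:
        raise ValueError("HR and SBP series share no time support")
    h, s = hr.values[ia], sbp.values[ib]
    num, den = (h, s) if si_definition == "hr_over_sbp" else (s, h)
    with np.errstate(divide="ignore", invalid="ignore"):
        si = np.where(np.isfinite(num) & np.isfinite(den) & (den != 0), num / den, np.nan)
    return NumericVitalSeries("SI", tt, si)


# ---------------------------------------------------------------------------
# HRV time domain
# ---------------------------------------------------------------------------

_TIME_NAMES = ("mean_nn", "sdnn", "rmssd", "nn50", "pnn50", "cv")


def hrv_time_domain(rr: BeatIntervalSeries, prefix: str = "") -> FeatureVector:
    """Mean NN, SDNN, RMSSD, NN50, pNN50 (in %), coefficient of variation."""
    fv = FeatureVector()
    pre = prefix or rr.source.lower()
    x = rr.intervals_ms
    if x.size < 10:
        for n in _TIME_NAMES:
            fv.set_missing(f"{pre}_{n}", rr.source)
        return fv
    d = np.diff(x)
    nn50 = int((np.abs(d) > 50.0).sum())
    vals = dict(
        mean_nn=x.mean(),
        sdnn=x.std(ddof=1),
        rmssd=float(np.sqrt(np.mean(d**2))),
        nn50=nn50,
        pnn50=100.0 * nn50 / d.size,
        cv=x.std(ddof=1) / x.mean(),
    )
    for n in _TIME_NAMES:
        fv.set(f"{pre}_{n}", vals[n], rr.source)
    return fv


# ---------------------------------------------------------------------------
# HRV frequency domain
# ---------------------------------------------------------------------------

_FREQ_NAMES = ("vlf_ms2", "lf_ms2", "hf_ms2", "lf_hf", "lf_nu", "hf_nu")
TACHOGRAM_HZ = 4.0


def _tachogram(rr: BeatIntervalSeries) -> tuple[np.ndarray, np.ndarray]:
    """Cubic interpolation of intervals onto a uniform 4 Hz grid, linearly
    detrended."""
    t = rr.interval_times
    x = rr.intervals_ms
    tg = np.arange(t[0], t[-1], 1.0 / TACHOGRAM_HZ)
    cs = CubicSpline(t, x)
    y = cs(tg)
    return tg, ssig.detrend(y, type="linear")


def _band_powers(freqs: np.ndarray, psd: np.ndarray, bands: SpectralBands) -> dict:
    out = {}
    for name, (lo, hi) in (("vlf", bands.vlf), ("lf", bands.lf), ("hf", bands.hf)):
        m = (freqs >= lo) & (freqs <= hi)
        out[name] = float(np.trapezoid(psd[m], freqs[m])) if m.sum() > 1 else 0.0
    return out


def _welch_psd(rr: BeatIntervalSeries):
    tg, y = _tachogram(rr)
    nperseg = min(y.size, 1024)
    return ssig.welch(
        y, fs=TACHOGRAM_HZ, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend=False, scaling="density",
    )


def lomb_power(t: np.ndarray, x: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Classic Lomb least-squares normalized power at the given frequencies.

    Vectorized closed form (time-offset tau per frequency); equals the
    classical periodogram ordinate |sum x e^{-iwt}|^2 / n for evenly sampled
    centered data.  Single precision internally (adequate for band powers).
    """
    t = np.asarray(t, dtype=np.float32)
    x = np.asarray(x, dtype=np.float32)
    w = (2.0 * np.pi * np.asarray(freqs, dtype=np.float32))[:, None]
    wt = w * t[None, :]
    c = np.cos(wt)
    s = np.sin(wt)
    xc = c @ x
    xs = s @ x
    cc = (c * c).sum(axis=1)
    cs = (c * s).sum(axis=1)
    nt = t.size
    c2w = 2.0 * cc - nt  # sum cos(2wt)
    s2w = 2.0 * cs  # sum sin(2wt)
    wtau = 0.5 * np.arctan2(s2w, c2w)
    ct, st = np.cos(wtau), np.sin(wtau)
    c2t = ct * ct - st * st
    s2t = 2.0 * st * ct
    xc_p = xc * ct + xs * st
    xs_p = xs * ct - xc * st
    cc_p = 0.5 * (nt + c2t * c2w + s2t * s2w)
    ss_p = 0.5 * (nt - c2t * c2w - s2t * s2w)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 0.5 * (xc_p**2 / cc_p + xs_p**2 / ss_p)
    return np.nan_to_num(p.astype(float))


def _lomb_psd(rr: BeatIntervalSeries, bands: SpectralBands):
    t = rr.interval_times
    x = rr.intervals_ms - rr.intervals_ms.mean()
    span = t[-1] - t[0]
    df = max(1.0 / span, 5e-4)  # Rayleigh resolution
    freqs = np.arange(max(df, bands.vlf[0] / 2), bands.hf[1] + 3 * df, df)
    p = lomb_power(t, x, freqs)
    # scale the Lomb ordinate to a one-sided PSD (ms^2/Hz): for even
    # sampling this equals the classical periodogram density
    psd = 2.0 * p * span / x.size
    return freqs, psd


def _burg_all_orders(x: np.ndarray, max_order: int):
    """Burg recursion; returns (coeffs, sigma2) for every order 1..max_order."""
    n = x.size
    f = x.astype(float).copy()
    b = x.astype(float).copy()
    a = np.zeros(max_order + 1)
    a[0] = 1.0
    sigma2 = float(np.mean(x**2))
    out = []
    for m in range(1, max_order + 1):
        ff = f[m:]
        bb = b[m - 1 : -1]
        denom = np.dot(ff, ff) + np.dot(bb, bb)
        k = -2.0 * np.dot(ff, bb) / denom if denom > 0 else 0.0
        # keep poles off the unit circle so the spectrum stays integrable
        # on a finite frequency grid (noiseless sinusoids drive |k| -> 1)
        k = float(np.clip(k, -0.995, 0.995))
        a_new = a.copy()
        a_new[1 : m + 1] = a[1 : m + 1] + k * a[0:m][::-1]
        a = a_new
        f_new = ff + k * bb
        b_new = bb + k * ff
        f[m:] = f_new
        b[m:] = b_new
        sigma2 *= 1.0 - k * k
        out.append((a[: m + 1].copy(), sigma2))
    return out


def _ar_psd(rr: BeatIntervalSeries, min_order=8, max_order=24, fallback=16):
    tg, y = _tachogram(rr)
    n = y.size
    max_order = min(max_order, n // 4)
    fits = _burg_all_orders(y, max_order)
    best = None
    for order in range(min_order, max_order + 1):
        a, s2 = fits[order - 1]
        if s2 <= 0:
            continue
        aic = n * np.log(s2) + 2.0 * order
        if best is None or aic < best[0]:
            best = (aic, a, s2)
    if best is None:
        a, s2 = fits[min(fallback, max_order) - 1]
    else:
        _, a, s2 = best
    nfft = 16384  # fine grid: near-unit-circle poles are narrow
    h = np.fft.rfft(a, nfft)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / TACHOGRAM_HZ)
    dt = 1.0 / TACHOGRAM_HZ
    psd = 2.0 * s2 * dt / np.abs(h) ** 2
    return freqs, psd


def hrv_frequency(
    rr: BeatIntervalSeries,
    method: str = "welch",
    bands: SpectralBands = SpectralBands(),
    prefix: str = "",
) -> FeatureVector:
    """Band powers (ms^2), LF/HF ratio, and normalized LF/HF by one method.

    Methods: ``welch`` (averaged periodograms of the uniform tachogram),
    ``lomb`` (least-squares spectrum on irregular beat times), ``ar``
    (Burg autoregressive spectrum, AIC order selection).  Requires at least
    60 s of intervals, otherwise all features are flagged missing.
    """
    if method not in ("welch", "lomb", "ar"):
        raise ValueError(f"unsupported spectral method {method!r}")
    pre = f"{prefix or rr.source.lower()}"
    fv = FeatureVector()
    names = [f"{pre}_{n}_{method}" for n in _FREQ_NAMES]
    t = rr.interval_times
    if t is None or t.size < 10 or (t[-1] - t[0]) < 60.0:
        for n in names:
            fv.set_missing(n, rr.source)
        return fv
    if np.ptp(rr.intervals_ms) == 0:
        powers = dict(vlf=0.0, lf=0.0, hf=0.0)
    else:
        if method == "welch":
            freqs, psd = _welch_psd(rr)
        elif method == "lomb":
            freqs, psd = _lomb_psd(rr, bands)
        else:
            freqs, psd = _ar_psd(rr)
        powers = _band_powers(freqs, psd, bands)
    lf, hf = powers["lf"], powers["hf"]
    tot = lf + hf
    vals = dict(
        vlf_ms2=powers["vlf"],
        lf_ms2=lf,
        hf_ms2=hf,
        lf_hf=lf / hf if hf > 0 else np.nan,
        lf_nu=100.0 * lf / tot if tot > 0 else np.nan,
        hf_nu=100.0 * hf / tot if tot > 0 else np.nan,
    )
    for base, full in zip(_FREQ_NAMES, names):
        fv.set(full, vals[base], f"{rr.source}/{method}")
    return fv


# ---------------------------------------------------------------------------
# HRV nonlinear
# ---------------------------------------------------------------------------

_NONLIN_NAMES = ("sampen", "sd1", "sd2", "sd1_sd2", "dfa_alpha1", "dfa_alpha2")


def sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """SampEn(m, r = r_frac * SD) with Chebyshev distance, self-matches
    excluded."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        return np.nan
    r = r_frac * x.std(ddof=1)
    if r <= 0:
        return np.nan
    xf = x.astype(np.float32)
    d0 = np.abs(xf[:, None] - xf[None, :])
    # chebyshev distances between length-m and length-(m+1) templates;
    # full symmetric count minus the diagonal, halved
    dm = np.maximum(d0[:-2, :-2], d0[1:-1, 1:-1])
    dm1 = np.maximum(dm, d0[2:, 2:])
    r32 = np.float32(r)
    b = (int((dm <= r32).sum()) - dm.shape[0]) // 2
    a = (int((dm1 <= r32).sum()) - dm1.shape[0]) // 2
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


def _dfa_alpha(x: np.ndarray, scales: np.ndarray) -> float:
    """DFA scaling exponent over the given window sizes (linear detrend)."""
    y = np.cumsum(x - x.mean())
    n = y.size
    fs = []
    used = []
    for s in scales:
        nwin = n // s
        if nwin < 2:
            continue
        segs = y[: nwin * s].reshape(nwin, s)
        t = np.arange(s, dtype=float)
        t -= t.mean()
        denom = (t**2).sum()
        slope = segs @ t / denom
        mean = segs.mean(axis=1)
        resid = segs - mean[:, None] - slope[:, None] * t[None, :]
        fs.append(np.sqrt(np.mean(resid**2)))
        used.append(s)
    if len(fs) < 3:
        return np.nan
    coef = np.polyfit(np.log(used), np.log(fs), 1)
    return float(coef[0])


def hrv_nonlinear(rr: BeatIntervalSeries, prefix: str = "") -> FeatureVector:
    """Sample entropy, Poincare SD1/SD2, and DFA alpha1/alpha2.

    Poincare needs >= 10 intervals; SampEn and DFA need >= 100.
    """
    fv = FeatureVector()
    pre = prefix or rr.source.lower()
    x = rr.intervals_ms
    vals = {n: np.nan for n in _NONLIN_NAMES}
    if x.size >= 10:
        d = np.diff(x)
        sd1 = float(np.sqrt(np.var(d) / 2.0))
        sd2sq = 2.0 * np.var(x) - sd1**2
        sd2 = float(np.sqrt(sd2sq)) if sd2sq > 0 else 0.0
        vals["sd1"], vals["sd2"] = sd1, sd2
        vals["sd1_sd2"] = sd1 / sd2 if sd2 > 0 else np.nan
    if x.size >= 100:
        vals["sampen"] = sample_entropy(x)
        vals["dfa_alpha1"] = _dfa_alpha(x, np.arange(4, 17))
        vals["dfa_alpha2"] = _dfa_alpha(x, np.unique(np.linspace(16, 64, 9).astype(int)))
    for n in _NONLIN_NAMES:
        fv.set(f"{pre}_{n}", vals[n], rr.source)
    return fv


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

_NUMERIC_ORDER = ("HR", "SpO2", "SBP", "DBP", "MBP", "RR")
_HRV_SOURCES = ("ecg", "ppg")
_FREQ_METHODS = ("welch", "lomb", "ar")


def assemble_features(
    numeric: dict[str, NumericVitalSeries],
    ecg_rr: Optional[BeatIntervalSeries] = None,
    ppg_rr: Optional[BeatIntervalSeries] = None,
    si_definition: str = "hr_over_sbp",
    bands: SpectralBands = SpectralBands(),
) -> FeatureVector:
    """Full per-patient feature vector in deterministic order.

    Unavailable sources produce flagged-missing features (imputation is the
    model layer's concern).  Demographics are deliberately not included.
    """
    fv = FeatureVector()
    for ch in _NUMERIC_ORDER:
        if ch in numeric:
            fv.update(descriptive_stats(numeric[ch]))
        else:
            fv.update(descriptive_stats(NumericVitalSeries(ch, [], [])))
    for spec in STANDARD_DOSES:
        name = f"dose_{spec.channel.lower()}_{spec.direction}_{spec.threshold:g}"
        if spec.channel in numeric:
            fv.set(name, dose(numeric[spec.channel], spec), spec.channel)
        else:
            fv.set_missing(name, spec.channel)
    # shock index: derived series gets descriptive stats and a dose above 1
    if (
        "HR" in numeric
        and "SBP" in numeric
        and numeric["HR"].times.size
        and numeric["SBP"].times.size
    ):
        si = shock_index_series(numeric["SBP"], numeric["HR"], si_definition)
        fv.update(descriptive_stats(si, prefix="si"))
        fv.set("dose_si_above_1", dose(si, DoseSpec("SI", 1.0, "above")), "SI")
    else:
        fv.update(descriptive_stats(NumericVitalSeries("SI", [], []), prefix="si"))
        fv.set_missing("dose_si_above_1", "SI")
    for src, rr in zip(_HRV_SOURCES, (ecg_rr, ppg_rr)):
        if rr is None or rr.intervals_ms.size == 0 or rr.unreliable:
            rr = BeatIntervalSeries(np.array([]), np.array([]), source=src.upper())
        fv.update(hrv_time_domain(rr, prefix=src))
        for method in _FREQ_METHODS:
            fv.update(hrv_frequency(rr, method=method, bands=bands, prefix=src))
        fv.update(hrv_nonlinear(rr, prefix=src))
    return fv


def feature_names() -> list[str]:
    """Canonical feature ordering (stable across runs and platforms)."""
    empty = {ch: NumericVitalSeries(ch, [], []) for ch in _NUMERIC_ORDER}
    return assemble_features(empty).names()
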