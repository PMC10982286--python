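"""Cleaning of raw numeric vitals and waveforms.

Three stages, applied in order before any feature extraction:

1. physiologic range filter on the 0.5 Hz numeric channels (samples outside
   per-channel admissible bounds are marked missing, never deleted);
2. 30 s centered median filter on the numeric channels;
3. robust penalized-least-squares smoothing of the 240 Hz waveforms in the
   DCT basis, with the smoothing parameter chosen by generalized
   cross-validation (GCV) and outliers down-weighted by bisquare weights.

The admission window is then enforced: series are truncated to the first 15
minutes and a patient is excluded when usable numeric coverage is below 5
minutes (the 5-minute minimum is inclusive).

Missing data are represented explicitly as NaN; no silent interpolation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Optional

import numpy as np
from scipy import fft as sfft

__all__ = [
    "NumericVitalSeries",
    "Waveform",
    "RangeLimits",
    "DEFAULT_LIMITS",
    "PatientSignals",
    "WindowResult",
    "filter_physiologic_range",
    "median_filter",
    "robust_smooth",
    "apply_admission_window",
]

NUMERIC_CHANNELS = ("HR", "SpO2", "SBP", "DBP", "MBP", "RR")


@dataclass
class NumericVitalSeries:
    """Timestamped 0.5 Hz numeric channel for one patient.

    ``values`` uses NaN for missing samples; ``times`` are seconds from
    admission and must be strictly increasing.
    """

    channel: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.values).sum())


@dataclass
class Waveform:
    """Uniformly sampled waveform (ECG or PPG)."""

    channel: str
    rate: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        self.samples = np.asarray(self.samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate


@dataclass
class PatientSignals:
    """All raw or cleaned series for one patient."""

    numeric: dict[str, NumericVitalSeries]
    ecg: Optional[Waveform] = None
    ppg: Optional[Waveform] = None
    rr_true: Optional[object] = None  # generator ground truth (BeatIntervalSeries)


@dataclass(frozen=True)
class RangeLimits:
    """Per-channel (lower, upper) admissible bounds, both inclusive."""

    bounds: Mapping[str, tuple[float, float]]

    def __post_init__(self):
        for ch, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"invalid bounds for {ch}: ({lo}, {hi})")

    def for_channel(self, channel: str) -> tuple[float, float]:
        if channel not in self.bounds:
            raise KeyError(f"no range limits configured for channel {channel!r}")
        return self.bounds[channel]


#: Upper bounds for HR/SBP/DBP follow the sensor-range rule (values above
#: 200 bpm / 250 mmHg / 200 mmHg are artifactual); lower bounds default to 0.
DEFAULT_LIMITS = RangeLimits(
    {
        "HR": (0.0, 200.0),
        "SBP": (0.0, 250.0),
        "DBP": (0.0, 200.0),
        "MBP": (0.0, 250.0),
        "SpO2": (0.0, 100.0),
        "RR": (0.0, 80.0),
    }
)


def filter_physiologic_range(
    series: NumericVitalSeries, limits: RangeLimits = DEFAULT_LIMITS
) -> tuple[NumericVitalSeries, int]:
    """Mark samples outside admissible bounds as missing.

    Returns the filtered series (timestamps preserved) and the number of
    samples removed.  Idempotent.
    """
    lo, hi = limits.for_channel(series.channel)
    v = series.values.copy()
    bad = np.isfinite(v) & ((v < lo) | (v > hi))
    v[bad] = np.nan
    return (
        NumericVitalSeries(series.channel, series.times.copy(), v),
        int(bad.sum()),
    )


def median_filter(series: NumericVitalSeries, window_s: float = 30.0) -> NumericVitalSeries:
    """Centered running median over a ``window_s`` time window.

    The window shrinks at the edges (no padding).  Missing samples are
    excluded from each window's median; a missing input sample stays missing
    in the output.  Output length equals input length.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    t, v = series.times, series.values
    if t.size == 0:
        raise ValueError("cannot median-filter an empty series")
    half = window_s / 2.0
    finite = np.isfinite(v)
    dt = np.diff(t)
    regular = t.size > 2 and np.allclose(dt, dt[0])
    if regular:
        # vectorized path: NaN-pad so edge windows shrink naturally
        k = int(np.floor(half / dt[0]))
        padded = np.concatenate([np.full(k, np.nan), v, np.full(k, np.nan)])
        windows = np.lib.stride_tricks.sliding_window_view(padded, 2 * k + 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = np.nanmedian(windows, axis=1)
        out[~finite] = np.nan
    else:
        lo = np.searchsorted(t, t - half, side="left")
        hi = np.searchsorted(t, t + half, side="right")
        out = np.full_like(v, np.nan)
        for i in range(t.size):
            if not finite[i]:
                continue
            w = v[lo[i] : hi[i]]
            w = w[np.isfinite(w)]
            out[i] = np.median(w)
    return NumericVitalSeries(series.channel, t.copy(), out)


# ---------------------------------------------------------------------------
# Robust DCT-penalized smoother
# ---------------------------------------------------------------------------

#: GCV search grid: 61 log-spaced smoothing parameters over [1e-3, 1e6].
_GCV_GRID = np.logspace(-3.0, 6.0, 61)


@lru_cache(maxsize=16)
def _laplacian_eigenvalues(n: int) -> np.ndarray:
    """Eigenvalues of the n-point Neumann (reflective) graph Laplacian,
    which the orthonormal DCT-II diagonalizes."""
    return 2.0 - 2.0 * np.cos(np.pi * np.arange(n) / n)


def _gcv_select(dy2: np.ndarray, lam2: np.ndarray, n: int) -> float:
    """Smoothing parameter minimizing GCV(s) = (RSS/n) / (1 - tr(H)/n)^2.

    ``dy2`` are squared DCT coefficients of the (weighted) signal, ``lam2``
    the squared Laplacian eigenvalues.  For long series the spectrum is
    binned (quadrature over ~1500 bins) before the grid search; the GCV
    surface is smooth in s so binning does not move the selected grid point
    materially.
    """
    m = dy2.size
    if m > 4096:
        # keep the low-frequency coefficients exact (the GCV transition
        # region), bin the remainder uniformly
        n_exact = 1024
        nbin = 1024
        edges = np.linspace(n_exact, m, nbin + 1).astype(int)
        counts = np.diff(edges)
        hi_dy2 = np.add.reduceat(dy2[n_exact:], edges[:-1] - n_exact)
        hi_lam2 = np.add.reduceat(lam2[n_exact:], edges[:-1] - n_exact) / counts
        dy2 = np.concatenate([dy2[:n_exact], hi_dy2])
        lam2 = np.concatenate([lam2[:n_exact], hi_lam2])
        w = np.concatenate([np.ones(n_exact), counts.astype(float)])
    else:
        w = np.ones_like(dy2)

    best_s, best_g = _GCV_GRID[0], np.inf
    for s in _GCV_GRID:
        gamma = 1.0 / (1.0 + s * lam2)
        rss = np.sum((1.0 - gamma) ** 2 * dy2)
        trh = np.sum(gamma * w)
        g = (rss / n) / (1.0 - trh / n) ** 2
        if g < best_g:
            best_g, best_s = g, s
    return float(best_s)


def _dct_solve(y: np.ndarray, s: float) -> np.ndarray:
    """Solve (I + s L^2) z = y in the DCT-II basis."""
    lam2 = _laplacian_eigenvalues(y.size) ** 2
    dy = sfft.dct(y, norm="ortho")
    return sfft.idct(dy / (1.0 + s * lam2), norm="ortho")


def robust_smooth(
    wave: Waveform,
    max_iter: int = 6,
    tol: float = 1e-3,
    s: Optional[float] = None,
) -> Waveform:
    """Penalized least-squares smoothing in the DCT basis, robust to spikes.

    Minimizes ||W^(1/2)(y - z)||^2 + s ||D z||^2 where D is the
    second-difference operator with reflective boundaries, solved via the
    DCT-II diagonalization.  A best-fit line is removed first and restored
    afterwards, so exactly linear signals (the penalty null space) pass
    through unchanged.  The smoothing parameter is selected by GCV on a
    61-point log grid over [1e-3, 1e6] unless ``s`` is given.

    Robustness: residuals are standardized by 1.4826*MAD and given bisquare
    weights; the weighted problem is re-solved until the relative change of
    the iterate falls below ``tol``.  If no residual exceeds the bisquare
    cutoff after the initial fit (all weights ~1), the plain GCV solution is
    returned directly.  Non-convergence after ``max_iter`` emits a warning
    and returns the last iterate.
    """
    y0 = np.asarray(wave.samples, dtype=float)
    n0 = y0.size
    if n0 < 8:
        raise ValueError("robust_smooth requires at least 8 samples")
    if not np.all(np.isfinite(y0)):
        raise ValueError("waveform samples must be finite")

    # long series: reflect-pad to a DCT-friendly length (the raw length can
    # have large prime factors that make the transform several times slower)
    pad = 0
    y = y0
    if n0 > 4096:
        # quantize the padded length so similar-length records share one
        # cached transform plan
        target = sfft.next_fast_len(-(-n0 // 8192) * 8192, real=True)
        pad = target - n0
        if pad:
            y = np.concatenate([y0, y0[-2 : -2 - pad : -1]])
    n = y.size

    # remove linear trend (restored at the end)
    x = np.arange(n, dtype=float)
    xc = x - x.mean()
    slope = (xc @ y) / (xc @ xc)
    intercept = y.mean()
    trend = intercept + slope * xc
    r = y - trend

    lam2 = _laplacian_eigenvalues(n) ** 2
    dy = sfft.dct(r, norm="ortho")
    s_val = _gcv_select(dy * dy, lam2, n) if s is None else float(s)
    gamma = 1.0 / (1.0 + s_val * lam2)
    z = sfft.idct(gamma * dy, norm="ortho")

    c_bisq = 4.685
    resid = r - z
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = 1.4826 * mad if mad > 0 else 0.0
    # reweight only when exceedances of the bisquare cutoff are clearly more
    # frequent than Gaussian chance (P(|z| > 4.685) ~ 3e-6)
    outlier_frac = np.mean(np.abs(resid) > c_bisq * scale) if scale > 0 else 0.0
    if scale > 0 and outlier_frac > 1e-4:
        w = np.ones(n)
        converged = False
        for _ in range(max_iter):
            u = np.abs(resid) / (scale * c_bisq)
            w = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
            # fixed point for the weighted system: z <- S(w*(r - z) + z)
            z_prev = z
            for _ in range(2):
                z = sfft.idct(
                    gamma * sfft.dct(w * (r - z) + z, norm="ortho"), norm="ortho"
                )
            denom = np.linalg.norm(z_prev) or 1.0
            resid = r - z
            mad = np.median(np.abs(resid - np.median(resid)))
            scale = 1.4826 * mad if mad > 0 else scale
            if np.linalg.norm(z - z_prev) / denom < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                "robust_smooth did not converge; returning last iterate",
                RuntimeWarning,
            )

    out = z + trend
    if pad:
        out = out[:n0]
    return Waveform(wave.channel, wave.rate, out, wave.t0)


# ---------------------------------------------------------------------------
# Admission window
# ---------------------------------------------------------------------------


@dataclass
class WindowResult:
    signals: PatientSignals
    excluded: bool
    coverage_minutes: float


def apply_admission_window(
    signals: PatientSignals,
    window_minutes: float = 15.0,
    min_minutes: float = 5.0,
) -> WindowResult:
    """Truncate all series to the first ``window_minutes`` and flag patients
    with less than ``min_minutes`` of usable numeric coverage (the minimum is
    inclusive: exactly 5 minutes passes)."""
    w_s = window_minutes * 60.0
    numeric = {}
    coverages = []
    for ch, s in signals.numeric.items():
        keep = s.times <= w_s
        ts, vs = s.times[keep], s.values[keep]
        numeric[ch] = NumericVitalSeries(ch, ts, vs)
        rate = 1.0 / np.median(np.diff(ts)) if ts.size > 1 else 0.0
        cov = (np.isfinite(vs).sum() / rate / 60.0) if rate > 0 else 0.0
        coverages.append(cov)

    def _cut(w: Optional[Waveform]) -> Optional[Waveform]:
        if w is None:
            return None
        n_keep = int(min(w.samples.size, round((w_s - w.t0) * w.rate)))
        return Waveform(w.channel, w.rate, w.samples[:n_keep], w.t0)

    coverage = float(min(coverages)) if coverages else 0.0
    out = PatientSignals(numeric, _cut(signals.ecg), _cut(signals.ppg), signals.rr_true)
    return WindowResult(out, excluded=coverage < min_minutes, coverage_minutes=coverage)
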