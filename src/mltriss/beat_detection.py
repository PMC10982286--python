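"""Beat detection on ECG and PPG waveforms and inter-beat artifact rejection.

The R-peak detector follows the classic derivative-energy scheme: band-pass
filter, differentiate, square, moving-window integration, adaptive threshold
on the integrated energy, then peak refinement on the band-passed signal.
PPG pulses are located as pulse peaks after low-pass filtering.  Both
detectors enforce a 250 ms physiologic refractory period and are invariant
to positive amplitude scaling (the threshold is a percentile of the energy
envelope).

``clean_intervals`` applies the usual normal-to-normal artifact rules:
intervals outside [300, 2000] ms or deviating more than 20% from a local
running median are rejected; a series losing more than half its intervals is
flagged unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as ssig
from scipy.ndimage import uniform_filter1d

from .preprocessing import Waveform

__all__ = [
    "BeatIntervalSeries",
    "CleaningRules",
    "detect_r_peaks",
    "detect_ppg_pulses",
    "clean_intervals",
]

REFRACTORY_S = 0.25


@dataclass
class BeatIntervalSeries:
    """Successive inter-beat intervals with their beat times.

    For raw detector output ``intervals_ms`` are the successive differences
    of ``beat_times`` (len = n_beats - 1).  After artifact rejection the kept
    intervals are a subset; ``interval_times`` records each kept interval's
    end-beat time so irregular-sampling spectral methods keep their support.
    """

    beat_times: np.ndarray
    intervals_ms: np.ndarray
    source: str = "ECG"
    n_rejected: int = 0
    unreliable: bool = False
    interval_times: Optional[np.ndarray] = None

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        if self.beat_times.size > 1 and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if np.any(self.intervals_ms <= 0):
            raise ValueError("intervals must be positive")
        if self.interval_times is None and self.beat_times.size > 1:
            self.interval_times = self.beat_times[1:]

    @classmethod
    def from_beat_times(cls, beat_times, source="ECG") -> "BeatIntervalSeries":
        bt = np.asarray(beat_times, dtype=float)
        iv = np.diff(bt) * 1000.0
        return cls(bt, iv, source=source)

    @property
    def n_beats(self) -> int:
        return self.beat_times.size

    @property
    def duration_s(self) -> float:
        if self.beat_times.size < 2:
            return 0.0
        return float(self.beat_times[-1] - self.beat_times[0])


def _empty(source: str) -> BeatIntervalSeries:
    return BeatIntervalSeries(np.array([]), np.array([]), source=source)


def _enforce_refractory(times: np.ndarray, strengths: np.ndarray) -> np.ndarray:
    """Greedy removal of detections closer than the refractory period,
    keeping the stronger of each conflicting pair."""
    if times.size < 2:
        return times
    order = np.argsort(times)
    times, strengths = times[order], strengths[order]
    kept_t, kept_s = [], []
    for t, s in zip(times, strengths):
        if kept_t and t - kept_t[-1] < REFRACTORY_S:
            if s > kept_s[-1]:
                kept_t[-1], kept_s[-1] = t, s
        else:
            kept_t.append(t)
            kept_s.append(s)
    return np.asarray(kept_t)


def detect_r_peaks(wave: Waveform) -> BeatIntervalSeries:
    """Locate R peaks on an ECG waveform.

    Requires a sampling rate of at least 100 Hz.  A flat or empty waveform
    yields an empty series (not an error).
    """
    if wave.channel.upper() != "ECG":
        raise ValueError("detect_r_peaks expects an ECG waveform")
    if wave.rate < 100:
        raise ValueError("ECG rate must be >= 100 Hz for R-peak detection")
    y = np.asarray(wave.samples, dtype=float)
    if y.size < int(wave.rate) or np.ptp(y[np.isfinite(y)] if y.size else y) == 0:
        return _empty("ECG")
    y = np.nan_to_num(y)

    fs = wave.rate
    sos = ssig.butter(2, [5.0, min(25.0, 0.45 * fs)], btype="band", fs=fs, output="sos")
    bp = ssig.sosfiltfilt(sos, y)
    energy = np.gradient(bp) ** 2
    integ = uniform_filter1d(energy, max(1, int(0.15 * fs)))

    thr = 0.20 * np.percentile(integ, 98)
    if thr <= 0:
        return _empty("ECG")
    locs, _ = ssig.find_peaks(integ, height=thr, distance=int(REFRACTORY_S * fs))
    if locs.size == 0:
        return _empty("ECG")

    # refine each detection to the extremum of the band-passed signal
    half = int(0.10 * fs)
    absbp = np.abs(bp)
    win = np.clip(locs[:, None] + np.arange(-half, half + 1)[None, :], 0, y.size - 1)
    refined = np.unique(win[np.arange(locs.size), np.argmax(absbp[win], axis=1)])
    t = wave.t0 + refined / fs
    t = _enforce_refractory(t, absbp[refined])
    if t.size < 2:
        return _empty("ECG")
    return BeatIntervalSeries.from_beat_times(t, source="ECG")


def detect_ppg_pulses(wave: Waveform) -> BeatIntervalSeries:
    """Locate pulse peaks on a PPG waveform.

    The landmark is the pulse maximum (clipped plateaus resolve to the
    plateau midpoint).
    """
    if wave.channel.upper() != "PPG":
        raise ValueError("detect_ppg_pulses expects a PPG waveform")
    y = np.asarray(wave.samples, dtype=float)
    if y.size < int(wave.rate) or np.ptp(y[np.isfinite(y)] if y.size else y) == 0:
        return _empty("PPG")
    y = np.nan_to_num(y)

    fs = wave.rate
    sos = ssig.butter(2, min(8.0, 0.45 * fs), btype="low", fs=fs, output="sos")
    lp = ssig.sosfiltfilt(sos, y)
    prom = 0.25 * (np.percentile(lp, 95) - np.percentile(lp, 5))
    if prom <= 0:
        return _empty("PPG")
    locs, props = ssig.find_peaks(
        lp, prominence=prom, distance=int(REFRACTORY_S * fs), plateau_size=0
    )
    # plateau midpoint for clipped pulses
    mids = (props["left_edges"] + props["right_edges"]) / 2.0
    t = wave.t0 + mids / fs
    t = _enforce_refractory(t, lp[locs])
    if t.size < 2:
        return _empty("PPG")
    return BeatIntervalSeries.from_beat_times(t, source="PPG")


@dataclass(frozen=True)
class CleaningRules:
    min_ms: float = 300.0
    max_ms: float = 2000.0
    local_median_tol: float = 0.20
    window: int = 11  # running-median window (odd)
    unreliable_fraction: float = 0.50


def clean_intervals(
    series: BeatIntervalSeries, rules: CleaningRules = CleaningRules()
) -> BeatIntervalSeries:
    """Reject artifact intervals and update the rejection count.

    An interval is rejected if it lies outside [min_ms, max_ms] or deviates
    from the running local median by more than ``local_median_tol``.  If more
    than half the intervals are rejected the result is flagged unreliable.
    """
    iv = series.intervals_ms
    if iv.size == 0:
        raise ValueError("cannot clean an empty interval series")
    tt = (
        series.interval_times
        if series.interval_times is not None
        else series.beat_times[1:]
    )

    ok_range = (iv >= rules.min_ms) & (iv <= rules.max_ms)
    if iv.size >= 3:
        k = min(rules.window, iv.size if iv.size % 2 == 1 else iv.size - 1)
        local_med = ssig.medfilt(iv, kernel_size=k)
        # shrinking windows at the edges
        h = k // 2
        for i in range(h):
            local_med[i] = np.median(iv[: i + h + 1])
            local_med[-(i + 1)] = np.median(iv[-(i + h + 1) :])
        ok_med = np.abs(iv - local_med) <= rules.local_median_tol * local_med
    else:
        ok_med = np.ones_like(ok_range)
    keep = ok_range & ok_med

    n_rej = int((~keep).sum())
    out = BeatIntervalSeries(
        beat_times=series.beat_times,
        intervals_ms=iv[keep],
        source=series.source,
        n_rejected=series.n_rejected + n_rej,
        unreliable=n_rej > rules.unreliable_fraction * iv.size,
        interval_times=tt[keep],
    )
    return out
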