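import numpy as np
import pytest
from hypothesis import settings

from mltriss.beat_detection import BeatIntervalSeries
from mltriss.preprocessing import NumericVitalSeries

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(values, channel="HR", dt=2.0):
    values = np.asarray(values, dtype=float)
    t = (np.arange(values.size) + 1) * dt
    return NumericVitalSeries(channel, t, values)


def make_rr(intervals_ms, source="ECG"):
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    bt = np.concatenate([[0.0], np.cumsum(intervals_ms) / 1000.0])
    # pass the intervals explicitly so they stay bit-exact
    return BeatIntervalSeries(bt, intervals_ms, source=source)


def matched_interval_errors(true_bt, det_bt, tol_s=0.15):
    """Per-interval absolute errors (ms) between true beats and their
    nearest detections, over consecutive matched pairs."""
    true_bt = np.asarray(true_bt)
    det_bt = np.asarray(det_bt)
    idx = np.searchsorted(det_bt, true_bt)
    idx = np.clip(idx, 1, det_bt.size - 1)
    nearer = np.where(
        np.abs(det_bt[idx] - true_bt) < np.abs(det_bt[idx - 1] - true_bt),
        idx,
        idx - 1,
    )
    ok = np.abs(det_bt[nearer] - true_bt) <= tol_s
    errs = []
    for k in range(true_bt.size - 1):
        if ok[k] and ok[k + 1] and nearer[k + 1] == nearer[k] + 1:
            true_iv = (true_bt[k + 1] - true_bt[k]) * 1000.0
            det_iv = (det_bt[nearer[k + 1]] - det_bt[nearer[k]]) * 1000.0
            errs.append(abs(det_iv - true_iv))
        else:
            errs.append(np.inf)  # missed or extra beat counts as an error
    return np.asarray(errs)
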