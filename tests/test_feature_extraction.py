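"""Descriptive stats, dose, shock index, and HRV feature oracles."""

import numpy as np
import pytest
from scipy import signal as ssig

from mltriss.beat_detection import BeatIntervalSeries
from mltriss.feature_extraction import (
    DoseSpec,
    SpectralBands,
    assemble_features,
    descriptive_stats,
    dose,
    feature_names,
    hrv_frequency,
    hrv_nonlinear,
    hrv_time_domain,
    lomb_power,
    sample_entropy,
    shock_index_series,
)
from mltriss.preprocessing import NumericVitalSeries
from mltriss.synthetic_data import RrModulation, generate_rr_series
from tests.conftest import make_rr, make_series


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------


def test_descriptive_stats_constant_series():
    fv = descriptive_stats(make_series(np.full(20, 80.0), "HR"))
    assert fv.values["hr_mean"] == 80
    assert fv.values["hr_sd"] == 0
    assert fv.values["hr_median"] == 80
    assert fv.values["hr_iqr"] == 0
    assert fv.values["hr_min"] == 80
    assert fv.values["hr_max"] == 80


def test_descriptive_stats_hand_case():
    fv = descriptive_stats(make_series([70.0, 80.0, 90.0], "HR"))
    assert fv.values["hr_mean"] == pytest.approx(80.0)
    assert fv.values["hr_median"] == pytest.approx(80.0)
    assert fv.values["hr_sd"] == pytest.approx(10.0)


def test_descriptive_stats_iqr_matches_sorted_array_oracle(rng):
    vals = np.arange(1.0, 101.0)
    rng.shuffle(vals)
    fv = descriptive_stats(make_series(vals, "SBP"))
    srt = np.sort(vals)
    # type-7 linear interpolation oracle computed by hand on the sorted array
    def q(p):
        h = (srt.size - 1) * p
        lo = int(np.floor(h))
        return srt[lo] + (h - lo) * (srt[min(lo + 1, srt.size - 1)] - srt[lo])

    assert fv.values["sbp_iqr"] == pytest.approx(q(0.75) - q(0.25), abs=1e-12)


def test_descriptive_stats_too_few_samples_flagged():
    fv = descriptive_stats(make_series([80.0], "HR"))
    assert "hr_mean" in fv.missing
    assert np.isnan(fv.values["hr_sd"])


# ---------------------------------------------------------------------------
# dose
# ---------------------------------------------------------------------------


def test_dose_constant_excess():
    s = make_series(np.full(301, 130.0))  # 602 s span at 2 s spacing
    assert dose(s, DoseSpec("HR", 120.0, "above")) == pytest.approx(10.0)


def test_dose_zero_when_never_crossing():
    s = make_series(np.full(100, 100.0))
    assert dose(s, DoseSpec("HR", 120.0, "above")) == 0.0


def test_dose_linear_ramp_triangle_case():
    """Ramp 110->130 over 600 s, threshold 120: triangle area / duration."""
    t = np.linspace(0.0, 600.0, 601)
    v = 110.0 + 20.0 * t / 600.0
    s = NumericVitalSeries("HR", t, v)
    assert dose(s, DoseSpec("HR", 120.0, "above")) == pytest.approx(2.5, abs=1e-9)


def test_dose_grid_refinement_invariance():
    """Trapezoid with crossing insertion is exact for piecewise-linear
    signals, so refining the grid leaves the dose unchanged."""
    for npts in (7, 61, 601):
        t = np.linspace(0.0, 600.0, npts)
        v = 110.0 + 20.0 * t / 600.0
        d = dose(NumericVitalSeries("HR", t, v), DoseSpec("HR", 120.0, "above"))
        assert d == pytest.approx(2.5, abs=1e-9)


def test_dose_below_direction():
    s = make_series(np.full(100, 80.0), "SpO2")
    assert dose(s, DoseSpec("SpO2", 88.0, "below")) == pytest.approx(8.0)


def test_dose_degenerate_span_missing():
    s = NumericVitalSeries("HR", [1.0], [100.0])
    assert np.isnan(dose(s, DoseSpec("HR", 120.0, "above")))


# ---------------------------------------------------------------------------
# shock index
# ---------------------------------------------------------------------------


def test_shock_index_conventional_ratio():
    hr = make_series(np.full(100, 120.0), "HR")
    sbp = make_series(np.full(100, 90.0), "SBP")
    si = shock_index_series(sbp, hr)
    np.testing.assert_allclose(si.values, 120.0 / 90.0)
    assert dose(si, DoseSpec("SI", 1.0, "above")) == pytest.approx(1 / 3, abs=1e-9)


def test_shock_index_boundary_equal():
    hr = make_series(np.full(50, 100.0), "HR")
    sbp = make_series(np.full(50, 100.0), "SBP")
    si = shock_index_series(sbp, hr)
    np.testing.assert_allclose(si.values, 1.0)
    assert dose(si, DoseSpec("SI", 1.0, "above")) == 0.0


def test_shock_index_literal_printed_ratio_option():
    hr = make_series(np.full(10, 120.0), "HR")
    sbp = make_series(np.full(10, 90.0), "SBP")
    si = shock_index_series(sbp, hr, si_definition="sbp_over_hr")
    np.testing.assert_allclose(si.values, 0.75)


def test_shock_index_missing_propagates():
    hr_vals = np.full(10, 100.0)
    hr_vals[3] = np.nan
    si = shock_index_series(
        make_series(np.full(10, 120.0), "SBP"), make_series(hr_vals, "HR")
    )
    assert np.isnan(si.values[3])
    assert np.isfinite(np.delete(si.values, 3)).all()


# ---------------------------------------------------------------------------
# HRV time domain
# ---------------------------------------------------------------------------


def test_hrv_time_constant_series():
    fv = hrv_time_domain(make_rr(np.full(50, 800.0)))
    assert fv.values["ecg_sdnn"] == 0
    assert fv.values["ecg_rmssd"] == 0
    assert fv.values["ecg_pnn50"] == 0


def test_hrv_time_alternating_series():
    fv = hrv_time_domain(make_rr(np.tile([800.0, 850.0], 20)))
    assert fv.values["ecg_rmssd"] == pytest.approx(50.0)
    # successive differences of exactly 50 ms do not count as NN50
    assert fv.values["ecg_pnn50"] == 0.0
    fv51 = hrv_time_domain(make_rr(np.tile([800.0, 851.0], 20)))
    assert fv51.values["ecg_pnn50"] == pytest.approx(100.0)


def test_hrv_time_matches_brute_force_oracle(rng):
    """SDNN/RMSSD/pNN50 equal a from-scratch recomputation on 100 series."""
    for _ in range(100):
        iv = rng.uniform(500, 1200, rng.integers(20, 200))
        fv = hrv_time_domain(make_rr(iv))
        d = np.diff(iv)
        assert fv.values["ecg_sdnn"] == pytest.approx(
            np.sqrt(np.sum((iv - iv.mean()) ** 2) / (iv.size - 1)), rel=1e-12
        )
        assert fv.values["ecg_rmssd"] == pytest.approx(
            np.sqrt(np.sum(d * d) / d.size), rel=1e-12
        )
        assert fv.values["ecg_pnn50"] == pytest.approx(
            100.0 * np.sum(np.abs(d) > 50) / d.size, rel=1e-12
        )


def test_hrv_time_too_few_intervals_flagged():
    fv = hrv_time_domain(make_rr(np.full(5, 800.0)))
    assert "ecg_sdnn" in fv.missing


# ---------------------------------------------------------------------------
# HRV frequency domain
# ---------------------------------------------------------------------------


def _as_ecg(rr):
    rr.source = "ECG"
    return rr


def _pure_lf_rr(seed=0):
    return _as_ecg(
        generate_rr_series(
            800.0,
            40.0,
            RrModulation(lf_freq=0.1, lf_frac=1.0, hf_frac=0.0, noise_frac=0.0),
            duration_s=300.0,
            seed=seed,
        )
    )


@pytest.mark.parametrize("method", ["welch", "lomb", "ar"])
def test_pure_lf_tone_power_localized(method):
    """A pure 0.1 Hz modulation puts >= 90% of its power in the LF band."""
    fv = hrv_frequency(_pure_lf_rr(), method=method)
    v = fv.values
    total = v[f"ecg_vlf_ms2_{method}"] + v[f"ecg_lf_ms2_{method}"] + v[f"ecg_hf_ms2_{method}"]
    assert total > 0
    assert v[f"ecg_lf_ms2_{method}"] / total >= 0.90


@pytest.mark.parametrize("method", ["welch", "lomb", "ar"])
def test_constant_rr_zero_band_power(method):
    rr = make_rr(np.full(200, 800.0))
    fv = hrv_frequency(rr, method=method)
    for band in ("vlf", "lf", "hf"):
        assert fv.values[f"ecg_{band}_ms2_{method}"] < 1e-6


def test_unsupported_method_rejected():
    with pytest.raises(ValueError):
        hrv_frequency(_pure_lf_rr(), method="burgx")


def test_insufficient_span_flagged():
    rr = make_rr(np.full(20, 800.0))  # 16 s span
    fv = hrv_frequency(rr, method="welch")
    assert f"ecg_lf_ms2_welch" in fv.missing


def test_lomb_equals_classical_periodogram_on_even_sampling(rng):
    """On an evenly sampled series the Lomb ordinate equals the classical
    periodogram at the Fourier frequencies within 1%."""
    n, dt = 512, 0.25
    t = np.arange(n) * dt
    x = (
        30 * np.sin(2 * np.pi * 0.08 * t)
        + 12 * np.sin(2 * np.pi * 0.27 * t + 0.8)
        + rng.normal(0, 5, n)
    )
    x = x - x.mean()
    freqs = np.fft.rfftfreq(n, dt)[1:-1]
    classical = np.abs(np.fft.rfft(x)[1:-1]) ** 2 / n
    lomb = lomb_power(t, x, freqs)
    keep = classical > 1e-3 * classical.max()  # compare where power is nonzero
    np.testing.assert_allclose(lomb[keep], classical[keep], rtol=0.01)


def test_welch_total_power_parseval_bound():
    """VLF+LF+HF <= tachogram variance * 1.05 for the Welch method."""
    rr = _as_ecg(generate_rr_series(800, 45, duration_s=600, seed=5))
    fv = hrv_frequency(rr, method="welch")
    total = sum(fv.values[f"ecg_{b}_ms2_welch"] for b in ("vlf", "lf", "hf"))
    var = rr.intervals_ms.var(ddof=1)
    assert total <= 1.05 * var


def test_cross_method_lf_hf_agreement():
    """All three spectral methods agree on LF/HF within 20% on a clean
    two-tone series."""
    rr = _as_ecg(
        generate_rr_series(
            800.0,
            45.0,
            RrModulation(lf_freq=0.1, hf_freq=0.25, lf_frac=0.6, hf_frac=0.4, noise_frac=0.0),
            duration_s=600.0,
            seed=6,
        )
    )
    ratios = [
        hrv_frequency(rr, method=m).values[f"ecg_lf_hf_{m}"]
        for m in ("welch", "lomb", "ar")
    ]
    ref = np.median(ratios)
    for r in ratios:
        assert abs(r - ref) / ref < 0.20


# ---------------------------------------------------------------------------
# HRV nonlinear
# ---------------------------------------------------------------------------


def test_poincare_sd1_closed_form():
    # 21 intervals -> 20 successive differences of +/-50, balanced mean
    fv = hrv_nonlinear(make_rr(np.tile([800.0, 850.0], 11)[:21]))
    assert fv.values["ecg_sd1"] == pytest.approx(50.0 / np.sqrt(2), rel=1e-9)


def test_sampen_periodic_below_shuffled(rng):
    x = np.tile([800.0, 840.0, 900.0, 840.0], 60)
    shuffled = rng.permutation(x)
    assert sample_entropy(x) < sample_entropy(shuffled)


def test_dfa_white_noise_alpha_half(rng):
    fv = hrv_nonlinear(make_rr(800 + 30 * rng.standard_normal(1000)))
    assert 0.4 <= fv.values["ecg_dfa_alpha1"] <= 0.6


def test_nonlinear_insufficient_data_flagged():
    fv = hrv_nonlinear(make_rr(np.full(50, 800.0) + np.arange(50)))
    assert "ecg_sampen" in fv.missing  # needs >= 100 intervals
    assert np.isfinite(fv.values["ecg_sd1"])  # Poincare needs only 10


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _numeric_set(rng, n=450):
    t = (np.arange(n) + 1) * 2.0
    mk = lambda ch, base, sd: NumericVitalSeries(ch, t, base + rng.normal(0, sd, n))
    return {
        "HR": mk("HR", 80, 2),
        "SpO2": mk("SpO2", 97, 0.5),
        "SBP": mk("SBP", 120, 4),
        "DBP": mk("DBP", 75, 3),
        "MBP": mk("MBP", 90, 3),
        "RR": mk("RR", 16, 1),
    }


def test_assemble_complete_patient_no_missing(rng):
    rr = generate_rr_series(800, 40, duration_s=880, seed=1)
    fv = assemble_features(_numeric_set(rng), rr, rr)
    assert not fv.missing
    assert len(set(fv.names())) == len(fv.names())


def test_assemble_missing_ppg_flags_only_ppg_family(rng):
    rr = generate_rr_series(800, 40, duration_s=880, seed=2)
    fv = assemble_features(_numeric_set(rng), rr, None)
    assert all(m.startswith("ppg_") for m in fv.missing)
    assert any(m.startswith("ppg_sdnn") for m in fv.missing)


def test_assemble_deterministic(rng):
    rr = generate_rr_series(800, 40, duration_s=880, seed=3)
    num = _numeric_set(rng)
    a = assemble_features(num, rr, rr)
    b = assemble_features(num, rr, rr)
    assert a.names() == b.names()
    for k in a.values:
        assert a.values[k] == b.values[k] or (
            np.isnan(a.values[k]) and np.isnan(b.values[k])
        )


def test_feature_name_ordering_golden():
    """Canonical ordering is stable: spot-check structure and key names."""
    names = feature_names()
    assert names == feature_names()
    assert names[:6] == ["hr_mean", "hr_sd", "hr_median", "hr_iqr", "hr_min", "hr_max"]
    for required in (
        "mbp_min",
        "dose_hr_above_120",
        "dose_hr_below_60",
        "dose_spo2_below_88",
        "dose_mbp_below_50",
        "dose_si_above_1",
        "si_sd",
        "ecg_sdnn",
        "ppg_rmssd",
        "ecg_lf_hf_welch",
        "ecg_lf_hf_lomb",
        "ecg_lf_hf_ar",
        "ppg_dfa_alpha1",
        "ecg_sampen",
    ):
        assert required in names
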