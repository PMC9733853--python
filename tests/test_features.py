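"""Feature extraction: dimension contracts, closed-form cases, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from elwhar.features import (
    BAND_STAT_NAMES,
    STAT_NAMES,
    FeatureMatrix,
    band_features,
    build_feature_matrix,
    butterworth_lowpass,
    dwt_decompose,
    dwt_max_level,
    freq_features,
    stats9,
    time_features,
    timefreq_features,
)
from elwhar.windowing import Window


def _window(samples, label="sitting", fs=32.0):
    return Window("S", label, 0.0, samples, fs)


def _rand_window(rng, L=128):
    return _window(rng.normal(0, 0.3, size=(L, 3)))


# ---------------------------------------------------------------------------
# Butterworth low-pass


def test_butterworth_passes_constant_unchanged():
    y = butterworth_lowpass(np.full(256, 2.5), fs=32)
    assert np.abs(y - 2.5).max() < 1e-6 * 2.5


def test_butterworth_attenuates_15hz_and_matches_frequency_response():
    # the analog prototype gives |H(15)| = (1 + 1.5^8)^-0.5 ~ 0.19; the
    # digital filter attenuates even harder near Nyquist, so < 0.25 holds
    # with a wide margin; the time-domain measurement must agree with the
    # filter's computed frequency response
    from scipy import signal as sps

    t = np.arange(4096) / 32.0
    x = np.sin(2 * np.pi * 15 * t)
    y = butterworth_lowpass(x, fs=32)
    steady = slice(1024, None)
    ratio = np.sqrt(np.mean(y[steady] ** 2)) / np.sqrt(np.mean(x[steady] ** 2))
    assert ratio < 0.25
    sos = sps.butter(4, 10, btype="low", fs=32, output="sos")
    _, h = sps.sosfreqz(sos, worN=[15.0], fs=32)
    assert ratio == pytest.approx(abs(h[0]), rel=0.1)


def test_butterworth_gain_at_cutoff_is_minus_3db():
    from scipy import signal as sps

    sos = sps.butter(4, 10, btype="low", fs=32, output="sos")
    _, h = sps.sosfreqz(sos, worN=[10.0], fs=32)
    gain_db = 20 * np.log10(abs(h[0]))
    assert gain_db == pytest.approx(-3.01, abs=0.5)


def test_butterworth_passes_1hz_within_2_percent():
    t = np.arange(2048) / 32.0
    x = np.sin(2 * np.pi * 1.0 * t)
    y = butterworth_lowpass(x, fs=32)
    steady = slice(512, None)
    ratio = np.sqrt(np.mean(y[steady] ** 2)) / np.sqrt(np.mean(x[steady] ** 2))
    assert abs(ratio - 1.0) < 0.02


def test_butterworth_rejects_cutoff_at_nyquist():
    with pytest.raises(ValueError):
        butterworth_lowpass(np.zeros(128), fs=32, fc=16)


# ---------------------------------------------------------------------------
# stats9


def test_stats9_constant_signal():
    s = stats9(np.full(50, 3.0))
    assert s.mean == s.rms == s.min == s.max == s.median == s.p25 == s.p75 == 3.0
    assert s.mad == s.sd == 0.0


def test_stats9_plus_minus_one():
    s = stats9(np.array([-1.0, 1.0]))
    assert s.mean == 0.0
    assert s.rms == 1.0
    assert s.mad == 1.0
    assert s.min == -1.0 and s.max == 1.0


def test_stats9_rejects_short_input():
    with pytest.raises(ValueError):
        stats9(np.array([1.0]))


@settings(deadline=None, max_examples=50)
@given(
    x=arrays(
        float,
        st.integers(min_value=2, max_value=200),
        elements=st.floats(-100, 100, allow_nan=False),
    )
)
def test_stats9_invariants(x):
    s = stats9(x)
    assert s.min <= s.p25 <= s.median <= s.p75 <= s.max
    assert s.rms + 1e-12 >= abs(s.mean)
    assert s.sd >= 0 and s.mad >= 0
    assert s.rms**2 + 1e-9 >= s.mean**2


def test_stats9_is_permutation_invariant(rng):
    x = rng.normal(size=100)
    a = stats9(x).as_array()
    b = stats9(rng.permutation(x)).as_array()
    assert np.allclose(a, b)


# ---------------------------------------------------------------------------
# time features


def test_time_features_dimension_is_27(rng):
    fv = time_features(_rand_window(rng))
    assert len(fv.values) == len(fv.names) == 27
    assert fv.names[:9] == [f"x_{s}" for s in STAT_NAMES]


def test_time_features_of_zero_window_are_zero():
    fv = time_features(_window(np.zeros((128, 3))))
    assert np.allclose(fv.values, 0.0)


# ---------------------------------------------------------------------------
# frequency features


@pytest.mark.parametrize("L, dim", [(128, 120), (320, 300)])
def test_freq_feature_dimensions(rng, L, dim):
    fv = freq_features(_rand_window(rng, L))
    assert len(fv.values) == len(fv.names) == dim


def test_freq_features_of_zero_window_are_zero():
    fv = freq_features(_window(np.zeros((128, 3))))
    assert np.allclose(fv.values, 0.0)


def test_freq_features_pure_sinusoid_closed_form():
    # integer-period sinusoid at 2 Hz on X: bin magnitude = N*A/2, rest ~ 0
    L, fs, A, f = 128, 32.0, 0.7, 2.0
    t = np.arange(L) / fs
    samples = np.zeros((L, 3))
    samples[:, 0] = A * np.sin(2 * np.pi * f * t)
    fv = freq_features(_window(samples))
    x_vals = fv.values[:40]
    k = int(f * L / fs)
    assert x_vals[k] == pytest.approx(L * A / 2, rel=1e-9)
    others = np.delete(x_vals, k)
    assert np.abs(others).max() < 1e-9 * L * A / 2 + 1e-9


def _dft_oracle(x):
    """Brute-force O(N^2) DFT magnitude."""
    N = x.size
    n = np.arange(N)
    return np.abs(
        np.array([(x * np.exp(-2j * np.pi * k * n / N)).sum() for k in range(N // 2 + 1)])
    )


def test_freq_features_match_brute_force_dft(rng):
    for _ in range(20):
        w = _rand_window(rng, 128)
        fv = freq_features(w)
        for ax in range(3):
            expected = _dft_oracle(w.samples[:, ax])[:40]
            got = fv.values[ax * 40 : (ax + 1) * 40]
            assert np.allclose(got, expected, rtol=1e-9, atol=1e-9)


# ---------------------------------------------------------------------------
# wavelet features


@pytest.mark.parametrize("L, level", [(128, 4), (320, 5)])
def test_dwt_max_level(L, level):
    assert dwt_max_level(L) == level


def test_dwt_max_level_too_short_errors():
    with pytest.raises(ValueError):
        dwt_max_level(8)  # floor(log2(8/7)) = 0: no admissible level
    with pytest.raises(ValueError):
        dwt_max_level(4)  # shorter than the filter itself


def test_dwt_round_trip(rng):
    x = rng.normal(size=128)
    bands = dwt_decompose(x)
    assert len(bands.bands) == 5  # cA4 + cD4..cD1
    err = np.abs(bands.reconstruct() - x).max()
    assert err < 1e-8 * np.ptp(x)


def test_dwt_constant_has_vanishing_details():
    bands = dwt_decompose(np.full(128, 5.0))
    for cd in bands.cD:
        assert np.abs(cd).max() < 1e-8 * 5.0


def test_dwt_level_too_deep_errors(rng):
    with pytest.raises(ValueError):
        dwt_decompose(rng.normal(size=128), level=5)


def test_band_features_single_nonzero_coefficient_entropy_zero():
    vals = band_features(np.array([0.0, 3.0, 0.0, 0.0]))
    assert vals[0] == 0.0  # entropy of a degenerate distribution


def test_band_features_alternating_signs():
    vals = band_features(np.array([1.0, -1.0, 1.0, -1.0]))
    names = dict(zip(BAND_STAT_NAMES, vals))
    assert names["zero_cross"] == 3
    assert names["mean_cross"] == 3


def test_band_features_uniform_magnitude_entropy_log_n():
    n = 16
    vals = band_features(np.ones(n))
    assert vals[0] == pytest.approx(np.log(n), rel=1e-12)


def test_band_features_empty_band_errors():
    with pytest.raises(ValueError):
        band_features(np.array([1.0]))


@pytest.mark.parametrize("L, dim", [(128, 180), (320, 216)])
def test_timefreq_feature_dimensions(rng, L, dim):
    fv = timefreq_features(_rand_window(rng, L))
    assert len(fv.values) == len(fv.names) == dim


def test_timefreq_zero_window_all_zero():
    fv = timefreq_features(_window(np.zeros((128, 3))))
    assert np.allclose(fv.values, 0.0)


@pytest.mark.parametrize("L", [64, 128, 256, 320])
def test_timefreq_dimension_formula_matches_enumeration(rng, L):
    fv = timefreq_features(_rand_window(rng, L))
    assert len(fv.values) == 3 * 12 * (dwt_max_level(L) + 1)


# ---------------------------------------------------------------------------
# feature matrices


def test_build_feature_matrix_shape_and_metadata(windows4):
    some = windows4[:45]
    fm = build_feature_matrix(some, "time")
    assert fm.values.shape == (45, 27)
    assert fm.domain == "time"
    for i, w in enumerate(some):
        assert fm.meta.loc[i, "subject_id"] == w.subject_id
        assert fm.meta.loc[i, "label"] == w.label
        assert fm.meta.loc[i, "start_s"] == w.start_s


def test_build_feature_matrix_rejects_empty_and_mixed(rng):
    with pytest.raises(ValueError):
        build_feature_matrix([], "time")
    w128, w320 = _rand_window(rng, 128), _rand_window(rng, 320)
    with pytest.raises(ValueError, match="mixed"):
        build_feature_matrix([w128, w320], "time")


def test_feature_matrix_csv_round_trip(tmp_path, time_matrix):
    path = tmp_path / "fm.csv"
    time_matrix.to_csv(path)
    back = FeatureMatrix.from_csv(path, domain="time", window_s=4)
    assert back.names == time_matrix.names
    assert np.allclose(back.values, time_matrix.values)
    assert (back.labels == time_matrix.labels).all()


def test_gravity_visible_in_means_but_not_in_magnitude(windows10):
    """Sitting and standing share the ~1 g magnitude but differ in per-axis
    means: orientation is what separates the static postures."""
    sit = [w for w in windows10 if w.label == "sitting"]
    stand = [w for w in windows10 if w.label == "standing"]
    mag = lambda ws: np.mean([np.linalg.norm(w.samples, axis=1).mean() for w in ws])
    assert abs(mag(sit) - mag(stand)) < 0.05
    fm_sit = build_feature_matrix(sit, "time")
    fm_stand = build_feature_matrix(stand, "time")
    mean_cols = [i for i, n in enumerate(fm_sit.names) if n.endswith("_mean")]
    diff = np.abs(
        fm_sit.values[:, mean_cols].mean(0) - fm_stand.values[:, mean_cols].mean(0)
    )
    assert diff.max() > 0.3  # well above the 0.02 g noise floor


def test_sitting_standing_centroids_separated_by_5_pooled_sd(windows10):
    sit = build_feature_matrix([w for w in windows10 if w.label == "sitting"], "time")
    stand = build_feature_matrix([w for w in windows10 if w.label == "standing"], "time")
    mean_cols = [i for i, n in enumerate(sit.names) if n.endswith("_mean")]
    gap = np.abs(sit.values[:, mean_cols].mean(0) - stand.values[:, mean_cols].mean(0))
    pooled_sd = np.sqrt(
        0.5 * (sit.values[:, mean_cols].var(0, ddof=1) + stand.values[:, mean_cols].var(0, ddof=1))
    )
    assert (gap >= 5 * pooled_sd).any()
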