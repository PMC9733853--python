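"""Per-window feature extraction in three domains.

* **time** — each axis is low-pass filtered (4th-order Butterworth, 10 Hz
  cutoff) and summarized by 9 statistics (mean, RMS, mean absolute deviation,
  standard deviation, min, max, median, 25th and 75th percentile): 27
  features per window.
* **freq** — magnitudes of the FFT coefficients of the raw axis signals at
  frequencies strictly below 10 Hz (DC included): 40 bins per axis for 4 s
  windows, 100 for 10 s, i.e. 120 / 300 features.
* **timefreq** — db4 discrete wavelet transform at the maximum admissible
  depth (4 levels for 128 samples, 5 for 320), with 12 descriptors (entropy,
  zero- and mean-crossings, plus the 9 statistics) per band: 180 / 216
  features.

The extractors are exposed both as plain functions on :class:`Window` objects
and as scikit-learn transformers over stacked ``(n, L, 3)`` sample arrays, so
they compose with pipelines and grid search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .tasks import AXES
from .windowing import Window

STAT_NAMES: tuple[str, ...] = (
    "mean",
    "rms",
    "mad",
    "sd",
    "min",
    "max",
    "median",
    "p25",
    "p75",
)

BAND_STAT_NAMES: tuple[str, ...] = ("entropy", "zero_cross", "mean_cross") + STAT_NAMES

DEFAULT_WAVELET = "db4"
DEFAULT_CUTOFF_HZ = 10.0


# ---------------------------------------------------------------------------
# primitives


def butterworth_lowpass(
    x: np.ndarray, fs: float, order: int = 4, fc: float = DEFAULT_CUTOFF_HZ
) -> np.ndarray:
    """Causal low-pass Butterworth filter with steady-state initialization.

    The filter state is initialized to the steady-state response for the first
    sample, so a constant input passes through unchanged (DC gain exactly 1)
    and edge transients are limited to genuine signal dynamics.
    """
    if fc >= fs / 2:
        raise ValueError(f"cutoff {fc} Hz must be below Nyquist {fs / 2} Hz")
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3 * order:
        raise ValueError(f"signal length {x.shape[0]} < 3 x filter order {order}")
    sos = sps.butter(order, fc, btype="low", fs=fs, output="sos")
    zi = sps.sosfilt_zi(sos) * x[0]
    y, _ = sps.sosfilt(sos, x, zi=zi)
    return y


@dataclass
class StatsSummary:
    """The 9 summary statistics of one 1-D signal."""

    mean: float
    rms: float
    mad: float
    sd: float
    min: float
    max: float
    median: float
    p25: float
    p75: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mean, self.rms, self.mad, self.sd, self.min, self.max,
             self.median, self.p25, self.p75]
        )


def stats9(x: np.ndarray) -> StatsSummary:
    """Mean, RMS, mean absolute deviation, sample sd (n-1), min, max, median
    and quartiles (linear interpolation) of a signal of length >= 2."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError(f"stats9 requires at least 2 samples, got {x.size}")
    m = float(np.mean(x))
    return StatsSummary(
        mean=m,
        rms=float(np.sqrt(np.mean(x**2))),
        mad=float(np.mean(np.abs(x - m))),
        sd=float(np.std(x, ddof=1)),
        min=float(np.min(x)),
        max=float(np.max(x)),
        median=float(np.median(x)),
        p25=float(np.percentile(x, 25)),
        p75=float(np.percentile(x, 75)),
    )


def dwt_max_level(n_samples: int, wavelet: str = DEFAULT_WAVELET) -> int:
    """Maximum admissible decomposition depth: floor(log2(n / (flen - 1))).

    For db4 (filter length 8): 128 samples -> 4 levels, 320 -> 5.
    """
    w = pywt.Wavelet(wavelet)
    if n_samples < w.dec_len:
        raise ValueError(
            f"signal of {n_samples} samples shorter than {wavelet} filter "
            f"({w.dec_len} taps)"
        )
    level = pywt.dwt_max_level(n_samples, w)
    if level < 1:
        raise ValueError(f"no admissible decomposition level for {n_samples} samples")
    return level


@dataclass
class WaveletBands:
    """One axis's DWT coefficient bands: cA at the deepest level, then detail
    bands from deepest (cD_L) to shallowest (cD_1)."""

    cA: np.ndarray
    cD: list[np.ndarray]  # [cD_L, ..., cD_1]
    wavelet: str
    level: int

    @property
    def bands(self) -> list[np.ndarray]:
        return [self.cA] + list(self.cD)

    @property
    def band_names(self) -> list[str]:
        return [f"cA{self.level}"] + [f"cD{self.level - i}" for i in range(self.level)]

    def reconstruct(self) -> np.ndarray:
        return pywt.waverec(self.bands, self.wavelet, mode="periodization")


def dwt_decompose(
    x: np.ndarray, wavelet: str = DEFAULT_WAVELET, level: int | None = None
) -> WaveletBands:
    """db4 filter-bank decomposition with periodic extension, so band lengths
    halve exactly and the inverse transform is numerically exact."""
    x = np.asarray(x, dtype=float)
    max_level = dwt_max_level(x.size, wavelet)
    if level is None:
        level = max_level
    if level > max_level:
        raise ValueError(f"level {level} exceeds maximum {max_level} for {x.size} samples")
    coeffs = pywt.wavedec(x, wavelet, mode="periodization", level=level)
    return WaveletBands(cA=coeffs[0], cD=list(coeffs[1:]), wavelet=wavelet, level=level)


def band_features(band: np.ndarray) -> np.ndarray:
    """12 descriptors of one coefficient band.

    Entropy is the Shannon entropy (natural log) of the normalized
    squared-coefficient distribution (0 for an all-zero band); zero crossings
    count strict sign changes between consecutive coefficients; mean
    crossings do the same after subtracting the band mean; the remaining 9
    are :func:`stats9`.
    """
    band = np.asarray(band, dtype=float)
    if band.size < 2:
        raise ValueError(f"band must have at least 2 coefficients, got {band.size}")
    energy = band**2
    total = energy.sum()
    if total > 0:
        p = energy / total
        nz = p[p > 0]
        entropy = float(-(nz * np.log(nz)).sum())
    else:
        entropy = 0.0
    zc = int(np.sum(np.sign(band[:-1]) * np.sign(band[1:]) < 0))
    centered = band - band.mean()
    mc = int(np.sum(np.sign(centered[:-1]) * np.sign(centered[1:]) < 0))
    return np.concatenate([[entropy, zc, mc], stats9(band).as_array()])


# ---------------------------------------------------------------------------
# feature vocabularies


def time_feature_names() -> list[str]:
    return [f"{ax}_{s}" for ax in AXES for s in STAT_NAMES]


def freq_feature_names(n_samples: int, fs: float, fmax: float = DEFAULT_CUTOFF_HZ) -> list[str]:
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    kept = freqs[freqs < fmax]
    return [f"{ax}_fft_{f:g}Hz" for ax in AXES for f in kept]


def timefreq_feature_names(n_samples: int, wavelet: str = DEFAULT_WAVELET) -> list[str]:
    level = dwt_max_level(n_samples, wavelet)
    band_names = [f"cA{level}"] + [f"cD{level - i}" for i in range(level)]
    return [f"{ax}_{b}_{s}" for ax in AXES for b in band_names for s in BAND_STAT_NAMES]


# ---------------------------------------------------------------------------
# containers


@dataclass
class FeatureVector:
    """Named features of one window in one domain."""

    domain: str
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names and values length mismatch")


@dataclass
class FeatureMatrix:
    """A stack of same-domain feature vectors with per-row window metadata."""

    values: np.ndarray  # (n, d)
    names: list[str]
    domain: str
    window_s: float
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)  # subject_id, label, start_s

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.names)} feature names"
            )
        if len(self.meta) != self.values.shape[0]:
            raise ValueError("metadata rows do not match feature rows")

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy()

    @property
    def subject_ids(self) -> np.ndarray:
        return self.meta["subject_id"].to_numpy()

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[mask],
            names=self.names,
            domain=self.domain,
            window_s=self.window_s,
            meta=self.meta.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask]
            .reset_index(drop=True),
        )

    def by_subject(self) -> dict[str, "FeatureMatrix"]:
        return {
            sid: self.subset((self.subject_ids == sid))
            for sid in pd.unique(self.meta["subject_id"])
        }

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        return pd.concat([self.meta.reset_index(drop=True), df], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, domain: str, window_s: float) -> "FeatureMatrix":
        df = pd.read_csv(path)
        meta_cols = ["subject_id", "label", "start_s"]
        names = [c for c in df.columns if c not in meta_cols]
        return cls(
            values=df[names].to_numpy(float),
            names=names,
            domain=domain,
            window_s=window_s,
            meta=df[meta_cols].copy(),
        )


# ---------------------------------------------------------------------------
# scikit-learn transformers over (n, L, 3) window stacks


class _WindowTransformer(TransformerMixin, BaseEstimator):
    """Base for stateless per-window extractors; ``fit`` only records the
    window length so feature names are available."""

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_samples_ = X.shape[1]
        self.feature_names_out_ = self._names(self.n_samples_)
        return self

    def transform(self, X):
        X = self._validate(X)
        if not hasattr(self, "n_samples_"):
            self.fit(X)
        if X.shape[1] != self.n_samples_:
            raise ValueError(
                f"window length {X.shape[1]} differs from fitted {self.n_samples_}"
            )
        return np.stack([self._one(w) for w in X])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_, dtype=object)

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != 3:
            raise ValueError(f"expected (n_windows, L, 3) array, got shape {X.shape}")
        if not np.isfinite(X).all():
            raise ValueError("windows contain NaN or Inf")
        return X


class TimeFeatureExtractor(_WindowTransformer):
    """27 time-domain features: stats9 of each low-pass filtered axis."""

    def __init__(self, fs: float = 32.0, order: int = 4, fc: float = DEFAULT_CUTOFF_HZ):
        self.fs = fs
        self.order = order
        self.fc = fc

    def _names(self, n_samples: int) -> list[str]:
        return time_feature_names()

    def _one(self, w: np.ndarray) -> np.ndarray:
        out = []
        for ax in range(3):
            filtered = butterworth_lowpass(w[:, ax], self.fs, self.order, self.fc)
            out.append(stats9(filtered).as_array())
        return np.concatenate(out)


class FrequencyFeatureExtractor(_WindowTransformer):
    """FFT coefficient magnitudes of the raw axis signals below ``fmax``."""

    def __init__(self, fs: float = 32.0, fmax: float = DEFAULT_CUTOFF_HZ):
        self.fs = fs
        self.fmax = fmax

    def _names(self, n_samples: int) -> list[str]:
        return freq_feature_names(n_samples, self.fs, self.fmax)

    def _one(self, w: np.ndarray) -> np.ndarray:
        L = w.shape[0]
        freqs = np.fft.rfftfreq(L, d=1.0 / self.fs)
        mask = freqs < self.fmax
        out = [np.abs(np.fft.rfft(w[:, ax]))[mask] for ax in range(3)]
        return np.concatenate(out)


class WaveletFeatureExtractor(_WindowTransformer):
    """db4 band statistics at maximum depth: 12 descriptors per band."""

    def __init__(self, wavelet: str = DEFAULT_WAVELET):
        self.wavelet = wavelet

    def _names(self, n_samples: int) -> list[str]:
        return timefreq_feature_names(n_samples, self.wavelet)

    def _one(self, w: np.ndarray) -> np.ndarray:
        out = []
        for ax in range(3):
            bands = dwt_decompose(w[:, ax], self.wavelet)
            for band in bands.bands:
                out.append(band_features(band))
        return np.concatenate(out)


_EXTRACTORS = {
    "time": TimeFeatureExtractor,
    "freq": FrequencyFeatureExtractor,
    "timefreq": WaveletFeatureExtractor,
}


def make_extractor(domain: str, fs: float = 32.0) -> _WindowTransformer:
    if domain not in _EXTRACTORS:
        raise ValueError(f"unknown feature domain {domain!r}; expected one of "
                         f"{sorted(_EXTRACTORS)}")
    if domain == "timefreq":
        return WaveletFeatureExtractor()
    return _EXTRACTORS[domain](fs=fs)


# ---------------------------------------------------------------------------
# window-level wrappers


def time_features(w: Window, fs: float | None = None) -> FeatureVector:
    fs = fs or w.sampling_rate
    ext = TimeFeatureExtractor(fs=fs)
    vals = ext.fit_transform(w.samples[None, :, :])[0]
    return FeatureVector(domain="time", names=time_feature_names(), values=vals)


def freq_features(w: Window, fs: float | None = None) -> FeatureVector:
    fs = fs or w.sampling_rate
    ext = FrequencyFeatureExtractor(fs=fs)
    vals = ext.fit_transform(w.samples[None, :, :])[0]
    return FeatureVector(
        domain="freq", names=freq_feature_names(w.samples.shape[0], fs), values=vals
    )


def timefreq_features(w: Window) -> FeatureVector:
    ext = WaveletFeatureExtractor()
    vals = ext.fit_transform(w.samples[None, :, :])[0]
    return FeatureVector(
        domain="timefreq",
        names=timefreq_feature_names(w.samples.shape[0]),
        values=vals,
    )


def build_feature_matrix(windows: list[Window], domain: str) -> FeatureMatrix:
    """Extract one domain's features for a list of same-length windows."""
    if not windows:
        raise ValueError("cannot build a feature matrix from zero windows")
    lengths = {w.samples.shape[0] for w in windows}
    if len(lengths) != 1:
        raise ValueError(f"mixed window lengths {sorted(lengths)}")
    rates = {w.sampling_rate for w in windows}
    if len(rates) != 1:
        raise ValueError(f"mixed sampling rates {sorted(rates)}")
    fs = windows[0].sampling_rate
    X = np.stack([w.samples for w in windows])
    ext = make_extractor(domain, fs=fs)
    values = ext.fit_transform(X)
    meta = pd.DataFrame(
        {
            "subject_id": [w.subject_id for w in windows],
            "label": [w.label for w in windows],
            "start_s": [w.start_s for w in windows],
        }
    )
    return FeatureMatrix(
        values=values,
        names=list(ext.feature_names_out_),
        domain=domain,
        window_s=windows[0].window_s,
        meta=meta,
    )
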