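"""Model interpretation: global importance, local surrogates, reconstruction.

Three complementary views of what the classifiers use:

* **Overall importance** — normalized mean-impurity-decrease importances from
  a fitted random forest (reported in full for the 27 time features, top 30
  for frequency, top 15 for time-frequency).
* **Class-specific importance** — a LIME-style local surrogate: Gaussian
  perturbations around an instance in standardized feature space, distance
  kernel weighting, a weighted ridge fit of the target-class score, and
  selection of the largest-magnitude coefficients; averaged over correctly
  classified windows of one task.
* **Reconstruction** — the selected frequency bins (with their conjugate
  partners) or wavelet bands are retained, everything else zeroed, and the
  inverse FFT / inverse DWT maps them back to an acceleration signal, showing
  which part of the raw motion the model keyed on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.pipeline import Pipeline

from .features import (
    FeatureMatrix,
    dwt_decompose,
    timefreq_feature_names,
)
from .tasks import AXES
from .windowing import Window

logger = logging.getLogger(__name__)

# Default report sizes per feature domain.
TOP_K = {"time": 27, "freq": 30, "timefreq": 15}


@dataclass
class ImportanceRanking:
    """Ordered (feature, weight) pairs; overall weights are nonnegative and
    sum to one, class-specific weights are signed surrogate coefficients."""

    entries: list[tuple[str, float]]
    scope: str  # "overall" or "class:<label>"
    provenance: dict = field(default_factory=dict)

    def top(self, k: int) -> list[tuple[str, float]]:
        return self.entries[:k]

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]


def _final_estimator(model):
    return model.steps[-1][1] if isinstance(model, Pipeline) else model


def rf_overall_importance(model, feature_names: list[str]) -> ImportanceRanking:
    """Impurity-decrease importances of a fitted forest, normalized to sum 1
    and sorted descending."""
    rf = _final_estimator(model)
    if not hasattr(rf, "feature_importances_"):
        raise ValueError("model is not a fitted tree ensemble with importances")
    imp = np.asarray(rf.feature_importances_, dtype=float)
    if len(feature_names) != imp.size:
        raise ValueError("feature_names length does not match the model")
    total = imp.sum()
    if total > 0:
        imp = imp / total
    order = np.argsort(-imp)
    return ImportanceRanking(
        entries=[(feature_names[i], float(imp[i])) for i in order],
        scope="overall",
        provenance={"model": type(rf).__name__, "n_trees": getattr(rf, "n_estimators", None)},
    )


@dataclass
class LimeConfig:
    """Local-surrogate settings: perturbation count, kernel width (default
    0.75 * sqrt(d) in standardized units), ridge penalty, number of retained
    features, and seed."""

    n_perturbations: int = 5000
    kernel_width: float | None = None
    ridge_alpha: float = 1.0
    n_selected: int | None = None
    seed: int = 0


@dataclass
class Explanation:
    """Signed local feature weights for one instance and one class."""

    instance_id: str
    target_class: str
    names: list[str]
    weights: np.ndarray  # full feature dimension; non-selected features are 0
    intercept: float
    kernel_width: float
    n_perturbations: int
    constant_output: bool = False


def _class_score(model, X: np.ndarray, target_class: str) -> np.ndarray:
    classes = list(getattr(model, "classes_", []))
    if target_class not in classes:
        raise ValueError(f"model does not know class {target_class!r}")
    col = classes.index(target_class)
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, col]
    if hasattr(model, "decision_function"):
        scores = model.decision_function(X)
        return scores[:, col] if scores.ndim == 2 else scores
    raise ValueError("model exposes neither predict_proba nor decision_function")


def lime_explain(
    model,
    instance: np.ndarray,
    background: FeatureMatrix | np.ndarray,
    target_class: str,
    cfg: LimeConfig | None = None,
    names: list[str] | None = None,
    instance_id: str = "",
) -> Explanation:
    """Fit a weighted linear surrogate to the model's class score around one
    instance.

    Perturbations are Gaussian in standardized feature space (scales taken
    from the background data); each is weighted by ``exp(-d^2 / kw^2)`` with
    ``d`` its standardized Euclidean distance from the instance.  A weighted
    ridge regression of the class score on the standardized offsets gives the
    local coefficients; if ``cfg.n_selected`` is set, the largest-magnitude
    coefficients are kept and the surrogate is refit on that subset.
    """
    cfg = cfg or LimeConfig()
    if isinstance(background, FeatureMatrix):
        names = names or background.names
        bg = background.values
    else:
        bg = np.asarray(background, dtype=float)
    if bg.size == 0:
        raise ValueError("background data is empty")
    instance = np.asarray(instance, dtype=float).ravel()
    d = instance.size
    if bg.shape[1] != d:
        raise ValueError("background dimension does not match the instance")
    names = names or [f"f{i}" for i in range(d)]
    scales = bg.std(axis=0, ddof=0)
    scales = np.where(scales > 1e-12, scales, 1.0)
    kw = cfg.kernel_width if cfg.kernel_width is not None else 0.75 * np.sqrt(d)

    rng = np.random.default_rng(cfg.seed)
    Z = rng.normal(size=(cfg.n_perturbations, d))
    Z[0] = 0.0  # keep the instance itself in the neighborhood
    X_pert = instance + Z * scales
    scores = _class_score(model, X_pert, target_class)
    if np.ptp(scores) < 1e-12:
        logger.warning("model output constant over the neighborhood; zero explanation")
        return Explanation(
            instance_id=instance_id,
            target_class=target_class,
            names=list(names),
            weights=np.zeros(d),
            intercept=float(scores[0]),
            kernel_width=kw,
            n_perturbations=cfg.n_perturbations,
            constant_output=True,
        )
    w = np.exp(-np.sum(Z**2, axis=1) / kw**2)
    ridge = Ridge(alpha=cfg.ridge_alpha)
    ridge.fit(Z, scores, sample_weight=w)
    coefs = ridge.coef_.copy()
    weights = np.zeros(d)
    if cfg.n_selected is not None and cfg.n_selected < d:
        sel = np.argsort(-np.abs(coefs))[: cfg.n_selected]
        ridge_sel = Ridge(alpha=cfg.ridge_alpha)
        ridge_sel.fit(Z[:, sel], scores, sample_weight=w)
        weights[sel] = ridge_sel.coef_
        intercept = float(ridge_sel.intercept_)
    else:
        weights = coefs
        intercept = float(ridge.intercept_)
    return Explanation(
        instance_id=instance_id,
        target_class=target_class,
        names=list(names),
        weights=weights,
        intercept=intercept,
        kernel_width=kw,
        n_perturbations=cfg.n_perturbations,
    )


def class_importance(
    model,
    matrix: FeatureMatrix,
    label: str,
    n_obs: int = 30,
    cfg: LimeConfig | None = None,
) -> ImportanceRanking:
    """Average the local surrogate weights over up to ``n_obs`` correctly
    classified windows of one task; rank features by mean |weight|."""
    cfg = cfg or LimeConfig()
    y_pred = model.predict(matrix.values)
    correct = np.flatnonzero((matrix.labels == label) & (y_pred == label))
    if correct.size == 0:
        raise ValueError(f"no correctly classified windows for class {label!r}")
    if correct.size < n_obs:
        logger.warning(
            "only %d correctly classified %r windows available (requested %d)",
            correct.size, label, n_obs,
        )
    chosen = correct[:n_obs]
    weight_sum = np.zeros(matrix.values.shape[1])
    # seed per observation follows its row index, so the average does not
    # depend on the order the observations are visited in
    for idx in chosen:
        exp = lime_explain(
            model,
            matrix.values[idx],
            matrix,
            label,
            cfg=LimeConfig(
                n_perturbations=cfg.n_perturbations,
                kernel_width=cfg.kernel_width,
                ridge_alpha=cfg.ridge_alpha,
                n_selected=cfg.n_selected,
                seed=cfg.seed + int(idx),
            ),
            instance_id=str(idx),
        )
        weight_sum += exp.weights
    mean_w = weight_sum / chosen.size
    order = np.argsort(-np.abs(mean_w))
    return ImportanceRanking(
        entries=[(matrix.names[i], float(mean_w[i])) for i in order],
        scope=f"class:{label}",
        provenance={"model": type(_final_estimator(model)).__name__, "n_obs": int(chosen.size)},
    )


@dataclass
class Reconstruction:
    """Per-axis reconstructed signals plus the retained components."""

    signals: np.ndarray  # (L, 3)
    retained: dict[str, list[str]]  # axis -> retained bins/bands
    domain: str


def full_freq_vocabulary(n_samples: int, fs: float) -> dict[str, tuple[int, int]]:
    """Map ``<axis>_fft_<freq>Hz`` names of every rFFT bin (DC to Nyquist) to
    (axis index, bin index)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    vocab = {}
    for ai, ax in enumerate(AXES):
        for k, f in enumerate(freqs):
            vocab[f"{ax}_fft_{f:g}Hz"] = (ai, k)
    return vocab


def reconstruct_from_freq(
    window: Window, selected: list[str], fs: float | None = None
) -> Reconstruction:
    """Zero every FFT bin not selected for its axis and invert.

    The rFFT representation keeps conjugate symmetry implicit, so the inverse
    transform is real by construction.  Selecting every bin of an axis
    reproduces that axis exactly.
    """
    fs = fs or window.sampling_rate
    L = window.samples.shape[0]
    vocab = full_freq_vocabulary(L, fs)
    unknown = [s for s in selected if s not in vocab]
    if unknown:
        raise ValueError(
            f"selected features {unknown} not in the frequency vocabulary of a "
            f"{L}-sample window (wrong window length?)"
        )
    keep: dict[int, set[int]] = {0: set(), 1: set(), 2: set()}
    for s in selected:
        ai, k = vocab[s]
        keep[ai].add(k)
    out = np.zeros_like(window.samples)
    retained: dict[str, list[str]] = {}
    for ai, ax in enumerate(AXES):
        F = np.fft.rfft(window.samples[:, ai])
        mask = np.zeros(F.size, dtype=bool)
        mask[sorted(keep[ai])] = True
        F[~mask] = 0.0
        out[:, ai] = np.fft.irfft(F, n=L)
        retained[ax] = [f"bin{k}" for k in sorted(keep[ai])]
    return Reconstruction(signals=out, retained=retained, domain="freq")


def reconstruct_from_dwt(window: Window, selected: list[str]) -> Reconstruction:
    """Retain every wavelet band containing at least one selected feature,
    zero the rest, and invert the DWT per axis."""
    L = window.samples.shape[0]
    vocab = set(timefreq_feature_names(L))
    unknown = [s for s in selected if s not in vocab]
    if unknown:
        raise ValueError(
            f"selected features {unknown} not in the wavelet vocabulary of a "
            f"{L}-sample window (wrong window length?)"
        )
    keep_bands: dict[str, set[str]] = {ax: set() for ax in AXES}
    for s in selected:
        ax, band, _ = s.split("_", 2)
        keep_bands[ax].add(band)
    out = np.zeros_like(window.samples)
    retained: dict[str, list[str]] = {}
    for ai, ax in enumerate(AXES):
        bands = dwt_decompose(window.samples[:, ai])
        kept = []
        coeffs = []
        for name, band in zip(bands.band_names, bands.bands):
            if name in keep_bands[ax]:
                coeffs.append(band)
                kept.append(name)
            else:
                coeffs.append(np.zeros_like(band))
        bands.cA = coeffs[0]
        bands.cD = coeffs[1:]
        rec = bands.reconstruct()
        out[:, ai] = rec[:L]
        retained[ax] = kept
    return Reconstruction(signals=out, retained=retained, domain="timefreq")
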