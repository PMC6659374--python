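"""Fully automated regression-based quantification.

Ridge models map binned spectral intensities to absolute line-shape-fit
signal areas; agreement with the reference fits is assessed by Bland-Altman
statistics, and spectra failing shimming/baseline QC are flagged before
training.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from .signatures_io import Spectrum

__all__ = [
    "FeatureWindow",
    "RegressionQuantModel",
    "AgreementReport",
    "DEFAULT_FEATURE_WINDOWS",
    "qc_spectrum",
    "extract_features",
    "train",
    "predict",
    "bland_altman",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class FeatureWindow:
    high_ppm: float
    low_ppm: float
    n_bins: int

    def __post_init__(self):
        if not self.high_ppm > self.low_ppm:
            raise ValueError("empty feature window")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


#: Packaged feature windows: the fit window plus flanking baseline context.
DEFAULT_FEATURE_WINDOWS = {
    "glucose": (
        FeatureWindow(5.45, 5.05, 40),
        FeatureWindow(5.70, 5.45, 8),
        FeatureWindow(5.05, 5.01, 4),
    ),
    "creatinine": (
        FeatureWindow(3.40, 2.90, 50),
        FeatureWindow(4.20, 3.85, 35),
        FeatureWindow(2.90, 2.80, 6),
    ),
}


@dataclass
class RegressionQuantModel:
    """Linear quantification model over binned intensities."""

    metabolite: str
    windows: tuple
    coefficients: np.ndarray
    intercept: float
    alpha: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = sum(w.n_bins for w in self.windows)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != n:
            raise ValueError(
                f"coefficient length {len(self.coefficients)} != total bins {n}"
            )


@dataclass
class AgreementReport:
    """Bland-Altman agreement between predicted and reference values."""

    n: int
    mean_bias: float
    loa_lower: float
    loa_upper: float
    slope: float            # predicted regressed on reference
    intercept: float
    r2: float
    bias_slope: float       # bias regressed on reference
    bias_intercept: float
    bias_r2: float

    def __post_init__(self):
        if not (self.loa_lower <= self.mean_bias <= self.loa_upper):
            raise ValueError("limits of agreement must bracket the mean bias")


def _quiet_zone_noise(spectrum: Spectrum) -> float:
    """Noise SD from first differences in signal-free zones."""
    diffs = []
    for hi, lo in ((10.0, 9.5), (-0.2, -0.45)):
        sl = spectrum.window_slice(hi, lo)
        seg = spectrum.intensity[sl]
        if len(seg) > 4:
            diffs.append(np.diff(seg))
    if not diffs:
        return float(np.std(np.diff(spectrum.intensity))) / math.sqrt(2)
    return float(np.std(np.concatenate(diffs))) / math.sqrt(2)


def _peak_fwhm_ppm(spectrum: Spectrum, high: float, low: float) -> float | None:
    """Interpolated full width at half maximum of the tallest peak in a zone."""
    sl = spectrum.window_slice(high, low)
    x, y = spectrum.ppm[sl], spectrum.intensity[sl]
    if len(y) < 5:
        return None
    i = int(np.argmax(y))
    top = y[i]
    base = float(np.median(y))
    half = base + (top - base) / 2.0
    if top <= base:
        return None
    left = right = None
    for k in range(i, 0, -1):
        if y[k - 1] < half <= y[k]:
            frac = (half - y[k - 1]) / (y[k] - y[k - 1])
            left = x[k - 1] + frac * (x[k] - x[k - 1])
            break
    for k in range(i, len(y) - 1):
        if y[k + 1] < half <= y[k]:
            frac = (half - y[k + 1]) / (y[k] - y[k + 1])
            right = x[k + 1] + frac * (x[k] - x[k + 1])
            break
    if left is None or right is None:
        return None
    return abs(left - right)


def qc_spectrum(spectrum: Spectrum, shimming_fwhm_hz: float = 1.8,
                baseline_factor: float = 20.0) -> dict:
    """Quality flags: broadened reference line (shimming), elevated level in
    signal-free zones (baseline), undetectable reference (tsp_missing).
    Flags only — the caller decides about exclusion."""
    noise = _quiet_zone_noise(spectrum)
    flags = {"shimming": False, "baseline": False, "tsp_missing": False}
    fwhm = _peak_fwhm_ppm(spectrum, 0.1, -0.1)
    sl = spectrum.window_slice(0.1, -0.1)
    tsp_height = float(np.max(spectrum.intensity[sl])) if sl.stop > sl.start else 0.0
    if tsp_height < 10.0 * max(noise, 1e-300):
        flags["tsp_missing"] = True
    elif fwhm is not None and fwhm * spectrum.frequency_mhz > shimming_fwhm_hz:
        flags["shimming"] = True
    zone = spectrum.window_slice(10.0, 9.5)
    level = float(np.median(np.abs(spectrum.intensity[zone]))) if zone.stop > zone.start else 0.0
    if level > baseline_factor * max(noise, 1e-300):
        flags["baseline"] = True
    return flags


def extract_features(spectrum: Spectrum, windows) -> np.ndarray:
    """Mean intensity per equal-width ppm bin, windows concatenated in order."""
    feats = []
    for w in windows:
        sl = spectrum.window_slice(w.high_ppm, w.low_ppm)
        x, y = spectrum.ppm[sl], spectrum.intensity[sl]
        if len(x) < w.n_bins:
            raise ValueError(
                f"window ({w.high_ppm}, {w.low_ppm}) outside axis or too few points"
            )
        edges = np.linspace(w.high_ppm, w.low_ppm, w.n_bins + 1)
        idx = np.clip(np.searchsorted(-edges, -x, side="right") - 1, 0, w.n_bins - 1)
        sums = np.bincount(idx, weights=y, minlength=w.n_bins)
        counts = np.bincount(idx, minlength=w.n_bins)
        counts[counts == 0] = 1
        feats.append(sums / counts)
    return np.concatenate(feats)


def _stratified_split(labels: np.ndarray, test_fraction: float, seed: int):
    """Deterministic split stratified by label tertile."""
    rng = np.random.default_rng(seed)
    n = len(labels)
    tert = np.searchsorted(np.quantile(labels, [1 / 3, 2 / 3]), labels)
    test_idx = []
    for t in np.unique(tert):
        members = np.flatnonzero(tert == t)
        rng.shuffle(members)
        k = int(round(len(members) * test_fraction))
        test_idx.extend(members[:k])
    test_mask = np.zeros(n, dtype=bool)
    test_mask[test_idx] = True
    return ~test_mask, test_mask


def train(spectra, labels, metabolite: str, windows=None,
          lambda_grid=(1e-8, 1e-6, 1e-4, 1e-2, 1.0, 100.0),
          test_fraction: float = 1 / 3, seed: int = 0, cv_folds: int = 5,
          qc_exclude: bool = True):
    """Fit a ridge model from spectra to reference signal areas.

    The penalty is chosen by ``cv_folds``-fold cross-validation on the
    training split (2:1 train/test by default, stratified by label tertile).
    Returns ``(RegressionQuantModel, AgreementReport)`` where the report is
    computed on the held-out split.
    """
    windows = tuple(windows or DEFAULT_FEATURE_WINDOWS[metabolite])
    labels = np.asarray(labels, dtype=float)
    if len(spectra) != len(labels):
        raise ValueError("spectra/labels length mismatch")
    keep = np.ones(len(labels), dtype=bool)
    if qc_exclude:
        keep = np.array([not any(qc_spectrum(s).values()) for s in spectra])
    spectra = [s for s, k in zip(spectra, keep) if k]
    labels = labels[keep]
    if len(labels) < 50:
        raise ValueError(f"need >= 50 usable spectra, have {len(labels)}")
    if np.std(labels) == 0:
        raise ValueError("degenerate labels: zero variance")

    x = np.vstack([extract_features(s, windows) for s in spectra])
    train_mask, test_mask = _stratified_split(labels, test_fraction, seed)
    xtr, ytr = x[train_mask], labels[train_mask]
    xte, yte = x[test_mask], labels[test_mask]

    # scale-aware penalty selection
    best_alpha, best_score = None, np.inf
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for alpha in lambda_grid:
        sse = 0.0
        for tr, va in kf.split(xtr):
            m = Ridge(alpha=alpha).fit(xtr[tr], ytr[tr])
            sse += float(np.sum((m.predict(xtr[va]) - ytr[va]) ** 2))
        if sse < best_score:
            best_score, best_alpha = sse, alpha
    final = Ridge(alpha=best_alpha).fit(xtr, ytr)
    model = RegressionQuantModel(
        metabolite=metabolite,
        windows=windows,
        coefficients=final.coef_,
        intercept=float(final.intercept_),
        alpha=float(best_alpha),
        metadata={
            "n_train": int(train_mask.sum()),
            "n_test": int(test_mask.sum()),
            "n_qc_excluded": int((~keep).sum()),
            "seed": seed,
            "cv_folds": cv_folds,
        },
    )
    pred = xte @ model.coefficients + model.intercept
    report = bland_altman(pred, yte)
    return model, report


def predict(model: RegressionQuantModel, spectrum: Spectrum) -> tuple:
    """Predict the signal area for one spectrum.

    Returns ``(area, clipped)``: negative predictions are clipped to zero
    and flagged rather than rejected.
    """
    feats = extract_features(spectrum, model.windows)
    raw = float(feats @ model.coefficients + model.intercept)
    if raw < 0:
        return 0.0, True
    return raw, False


def _safe_linregress(x, y):
    """linregress with the constant-y degenerate case mapped to slope 0,
    r 0 (scipy returns NaN there)."""
    if np.ptp(y) == 0:
        class _Flat:
            slope, intercept, rvalue = 0.0, float(y[0]), 0.0
        return _Flat()
    return stats.linregress(x, y)


def bland_altman(predicted, reference) -> AgreementReport:
    """Agreement statistics: mean bias, mean +/- 1.96 SD limits, the
    predicted-on-reference regression and the bias-on-reference regression."""
    pred = np.asarray(predicted, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if len(pred) != len(ref):
        raise ValueError("length mismatch")
    n = len(pred)
    if n < 3:
        raise ValueError("need n >= 3")
    d = pred - ref
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    fit_main = _safe_linregress(ref, pred)
    fit_bias = _safe_linregress(ref, d)
    return AgreementReport(
        n=n,
        mean_bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        slope=float(fit_main.slope),
        intercept=float(fit_main.intercept),
        r2=float(fit_main.rvalue**2),
        bias_slope=float(fit_bias.slope),
        bias_intercept=float(fit_bias.intercept),
        bias_r2=float(fit_bias.rvalue**2),
    )


def save_model(model: RegressionQuantModel, path) -> None:
    doc = {
        "metabolite": model.metabolite,
        "windows": [[w.high_ppm, w.low_ppm, w.n_bins] for w in model.windows],
        "coefficients": model.coefficients.tolist(),
        "intercept": model.intercept,
        "alpha": model.alpha,
        "metadata": model.metadata,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> RegressionQuantModel:
    with open(path) as fh:
        doc = json.load(fh)
    return RegressionQuantModel(
        metabolite=doc["metabolite"],
        windows=tuple(FeatureWindow(*w) for w in doc["windows"]),
        coefficients=np.asarray(doc["coefficients"]),
        intercept=float(doc["intercept"]),
        alpha=float(doc["alpha"]),
        metadata=doc.get("metadata", {}),
    )
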