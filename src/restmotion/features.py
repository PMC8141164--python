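"""Per-sensor feature extraction from detrended resultant signals.

Eighteen features per sensor, in fixed order: five amplitude measures
(rms, peak, mav, mavfd, mavsd), six frequency measures (fmean,
zero_crossing, fpeak, f50, f80, bandpower), two regularity measures
(apen, fuzzyen), three variability measures (variance, range, iqr) and
two distribution-shape measures (skewness, kurtosis).  A two-IMU
recording therefore yields 6 x 18 = 108 named values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigurationError, RestmotionError, ShapeError
from .preprocessing import DEFAULT_BAND, RESULTANT_ORDER, ResultantSignal, preprocess_recording
from .recording import IMURecording

#: Feature names in their canonical extraction order.
FEATURE_NAMES = (
    "rms",
    "peak",
    "mav",
    "mavfd",
    "mavsd",
    "fmean",
    "zero_crossing",
    "fpeak",
    "f50",
    "f80",
    "bandpower",
    "apen",
    "fuzzyen",
    "variance",
    "range",
    "iqr",
    "skewness",
    "kurtosis",
)

#: Tremor band limits for the band-power feature (Hz).
POWER_BAND = (3.5, 7.5)

#: Non-feature columns of a feature table.
META_COLUMNS = ("subject_id", "label", "hy")


class UndefinedFeatureError(RestmotionError):
    """Feature has no defined value on this input (e.g. zero-power spectrum)."""


@dataclass
class EntropyParams:
    """Shared parameters of the regularity statistics.

    ``r`` is expressed as a multiple of the signal's standard deviation,
    making both entropies scale-free.
    """

    m: int = 2
    r: float = 0.2
    fuzzy_power: int = 2

    def validate(self) -> None:
        if self.m < 1:
            raise ConfigurationError("embedding length m must be >= 1")
        if self.r <= 0:
            raise ConfigurationError("tolerance r must be positive")
        if self.fuzzy_power < 1:
            raise ConfigurationError("fuzzy exponent must be >= 1")


@dataclass
class SpectralEstimate:
    frequencies: np.ndarray
    power: np.ndarray

    @property
    def total_power(self) -> float:
        return float(self.power.sum())


@dataclass
class FeatureVector:
    """108 named feature values for one subject-trial."""

    names: list[str]
    values: np.ndarray
    label: str
    subject_id: str
    hy_score: int = 0

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def _as_signal(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ShapeError("expected a non-empty 1-D signal")
    return x


# ----------------------------------------------------------------- amplitude

def rms(x) -> float:
    x = _as_signal(x)
    return float(np.sqrt(np.mean(x * x)))


def peak(x) -> float:
    """Maximum value of the signal."""
    return float(np.max(_as_signal(x)))


def mav(x) -> float:
    """Mean absolute value; the window is the whole signal."""
    return float(np.mean(np.abs(_as_signal(x))))


def mavfd(x) -> float:
    """Mean absolute first difference."""
    x = _as_signal(x)
    if x.size < 2:
        raise ShapeError("mavfd needs at least 2 samples")
    return float(np.mean(np.abs(np.diff(x))))


def mavsd(x) -> float:
    """Mean absolute lag-2 difference."""
    x = _as_signal(x)
    if x.size < 3:
        raise ShapeError("mavsd needs at least 3 samples")
    return float(np.mean(np.abs(x[2:] - x[:-2])))


# ------------------------------------------------------------------ spectral

def power_spectrum(
    x, rate: float, estimator: str = "periodogram"
) -> SpectralEstimate:
    """One-sided power spectrum whose bin sum matches the mean square power.

    ``estimator`` selects a plain rectangular-window periodogram of the
    whole record (default) or Welch averaging.
    """
    x = _as_signal(x)
    if estimator == "periodogram":
        f, p = sps.periodogram(
            x, fs=rate, window="boxcar", detrend=False, scaling="spectrum"
        )
    elif estimator == "welch":
        f, p = sps.welch(
            x, fs=rate, nperseg=min(256, x.size), detrend=False, scaling="spectrum"
        )
    else:
        raise ConfigurationError(f"unknown spectrum estimator {estimator!r}")
    return SpectralEstimate(frequencies=f, power=p)


def _require_power(spec: SpectralEstimate) -> float:
    total = spec.total_power
    if total <= 0:
        raise UndefinedFeatureError("zero-power spectrum")
    return total


def fmean(spec: SpectralEstimate) -> float:
    """Power-weighted mean frequency."""
    total = _require_power(spec)
    return float((spec.power * spec.frequencies).sum() / total)


def fpeak(spec: SpectralEstimate) -> float:
    """Frequency of the maximum-power bin (first bin on ties)."""
    _require_power(spec)
    return float(spec.frequencies[int(np.argmax(spec.power))])


def _quantile_frequency(spec: SpectralEstimate, fraction: float) -> float:
    # first grid frequency at which cumulative power reaches the threshold
    total = _require_power(spec)
    cum = np.cumsum(spec.power)
    idx = int(np.searchsorted(cum, fraction * total))
    return float(spec.frequencies[min(idx, spec.frequencies.size - 1)])


def f50(spec: SpectralEstimate) -> float:
    return _quantile_frequency(spec, 0.5)


def f80(spec: SpectralEstimate) -> float:
    return _quantile_frequency(spec, 0.8)


def power_band(
    spec: SpectralEstimate, low: float = POWER_BAND[0], high: float = POWER_BAND[1]
) -> float:
    """Summed power of all bins with low <= f <= high."""
    mask = (spec.frequencies >= low) & (spec.frequencies <= high)
    return float(spec.power[mask].sum())


def zero_crossing(x) -> int:
    """Count strict sign changes; zeros inherit the preceding sign."""
    x = _as_signal(x)
    s = np.sign(x)
    nz = s != 0
    if not nz.any():
        return 0
    # forward-fill zero signs with the previous non-zero sign
    idx = np.where(nz, np.arange(x.size), -1)
    idx = np.maximum.accumulate(idx)
    valid = idx >= 0  # leading zeros carry no sign
    filled = s[idx[valid]]
    return int(np.count_nonzero(filled[1:] != filled[:-1]))


# ---------------------------------------------------------------- regularity

def _embed(x: np.ndarray, m: int) -> np.ndarray:
    return sliding_window_view(x, m)


def apen(x, params: EntropyParams = EntropyParams()) -> float:
    """Approximate entropy; self-matches included, Chebyshev distance.

    Tolerance is ``params.r`` times the signal SD.
    """
    params.validate()
    x = _as_signal(x)
    m = params.m
    if x.size <= m + 1:
        raise ShapeError(f"apen needs more than m+1={m + 1} samples")
    r = params.r * float(np.std(x))

    def phi(mm: int) -> float:
        vec = _embed(x, mm)
        within = squareform(pdist(vec, metric="chebyshev") <= r)
        # self-match (the diagonal) keeps every count >= 1
        c = (within.sum(axis=1) + 1) / vec.shape[0]
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def fuzzyen(x, params: EntropyParams = EntropyParams()) -> float:
    """Fuzzy entropy; self-matches excluded, per-vector baseline removed.

    Similarity is exp(-(d/r)^n) with Chebyshev d on baseline-removed
    vectors; vectors of both lengths are indexed 1..N-m so the counts
    match across embedding lengths.
    """
    params.validate()
    x = _as_signal(x)
    m = params.m
    if x.size <= m + 1:
        raise ShapeError(f"fuzzyen needs more than m+1={m + 1} samples")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0  # all vectors identical: similarity 1 at both lengths
    r = params.r * sd
    n_vec = x.size - m

    def phi(mm: int) -> float:
        vec = _embed(x, mm)[:n_vec]
        vec = vec - vec.mean(axis=1, keepdims=True)
        d = pdist(vec, metric="chebyshev")
        mu = np.exp(-((d / r) ** params.fuzzy_power))
        # mean over i of mean over j != i collapses to the mean of the
        # off-diagonal similarities, i.e. of the condensed matrix
        return float(2.0 * mu.sum() / (n_vec * (n_vec - 1)))

    return float(np.log(phi(m)) - np.log(phi(m + 1)))


# --------------------------------------------------- variability & shape

def variance(x) -> float:
    x = _as_signal(x)
    if x.size < 2:
        raise ShapeError("variance needs at least 2 samples")
    return float(np.var(x, ddof=1))


def range_(x) -> float:
    x = _as_signal(x)
    return float(np.max(x) - np.min(x))


def intla(x) -> float:
    """Interquartile range Q3 - Q1 with linear quantile interpolation."""
    x = _as_signal(x)
    q1, q3 = np.percentile(x, [25, 75])
    return float(q3 - q1)


def _std_unbiased(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1))


def skewness(x) -> float:
    """Third central moment (biased) over the cube of the n-1 SD."""
    x = _as_signal(x)
    if x.size < 2:
        raise ShapeError("skewness needs at least 2 samples")
    sd = _std_unbiased(x)
    if sd == 0:
        raise UndefinedFeatureError("skewness undefined for constant signal")
    return float(np.mean((x - x.mean()) ** 3) / sd**3)


def kurtosis(x) -> float:
    """Non-excess kurtosis (Gaussian ~ 3): fourth moment over the SD^4."""
    x = _as_signal(x)
    if x.size < 2:
        raise ShapeError("kurtosis needs at least 2 samples")
    sd = _std_unbiased(x)
    if sd == 0:
        raise UndefinedFeatureError("kurtosis undefined for constant signal")
    return float(np.mean((x - x.mean()) ** 4) / sd**4)


# ------------------------------------------------------------------ assembly

def compute_sensor_features(
    sig: ResultantSignal,
    params: EntropyParams = EntropyParams(),
    estimator: str = "periodogram",
) -> dict[str, float]:
    """The 18 features of one detrended resultant, NaN where undefined."""
    x = sig.samples
    spec = power_spectrum(x, sig.sampling_rate, estimator=estimator)
    producers = {
        "rms": lambda: rms(x),
        "peak": lambda: peak(x),
        "mav": lambda: mav(x),
        "mavfd": lambda: mavfd(x),
        "mavsd": lambda: mavsd(x),
        "fmean": lambda: fmean(spec),
        "zero_crossing": lambda: float(zero_crossing(x)),
        "fpeak": lambda: fpeak(spec),
        "f50": lambda: f50(spec),
        "f80": lambda: f80(spec),
        "bandpower": lambda: power_band(spec),
        "apen": lambda: apen(x, params),
        "fuzzyen": lambda: fuzzyen(x, params),
        "variance": lambda: variance(x),
        "range": lambda: range_(x),
        "iqr": lambda: intla(x),
        "skewness": lambda: skewness(x),
        "kurtosis": lambda: kurtosis(x),
    }
    out = {}
    for name in FEATURE_NAMES:
        try:
            out[name] = producers[name]()
        except UndefinedFeatureError as exc:
            warnings.warn(
                f"{sig.sensor_name}.{name} undefined: {exc}", stacklevel=2
            )
            out[name] = float("nan")
    return out


def extract_features(
    rec: IMURecording,
    params: EntropyParams = EntropyParams(),
    band: tuple[float, float] = DEFAULT_BAND,
    estimator: str = "periodogram",
) -> FeatureVector:
    """Preprocess a recording and emit its 108-entry feature vector."""
    names: list[str] = []
    values: list[float] = []
    for sig in preprocess_recording(rec, band=band):
        feats = compute_sensor_features(sig, params=params, estimator=estimator)
        for fname in FEATURE_NAMES:
            names.append(f"{sig.sensor_name}.{fname}")
            values.append(feats[fname])
    return FeatureVector(
        names=names,
        values=np.asarray(values, dtype=float),
        label=rec.group,
        subject_id=rec.subject_id,
        hy_score=rec.hy_score,
    )


def build_feature_table(
    cohort,
    params: EntropyParams = EntropyParams(),
    band: tuple[float, float] = DEFAULT_BAND,
    estimator: str = "periodogram",
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Feature table for a generated cohort.

    ``aggregate="mean"`` averages the per-trial vectors into one row per
    subject (the default); ``aggregate="trials"`` keeps one row per trial.
    """
    if aggregate not in ("mean", "trials"):
        raise ConfigurationError(f"unknown aggregation {aggregate!r}")
    rows = []
    for spec, recs in cohort:
        vectors = [
            extract_features(r, params=params, band=band, estimator=estimator)
            for r in recs
        ]
        if aggregate == "mean":
            stacked = np.vstack([v.values for v in vectors])
            row = {
                "subject_id": spec.subject_id,
                "label": spec.group,
                "hy": spec.hy_score,
            }
            row.update(zip(vectors[0].names, stacked.mean(axis=0)))
            rows.append(row)
        else:
            for k, v in enumerate(vectors, start=1):
                row = {
                    "subject_id": f"{spec.subject_id}/t{k}",
                    "label": spec.group,
                    "hy": spec.hy_score,
                }
                row.update(v.as_dict())
                rows.append(row)
    return pd.DataFrame(rows)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature columns of a table (everything non-meta)."""
    return [c for c in table.columns if c not in META_COLUMNS]
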