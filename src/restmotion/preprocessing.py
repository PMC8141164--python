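"""Turn raw triaxial streams into detrended resultant signals.

Per sensor: band-pass each axis (1-16 Hz, zero-phase Butterworth),
take the per-sample Euclidean magnitude of the three axes, then
subtract the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, ShapeError
from .recording import IMURecording

#: Fixed output order of the six resultants.
RESULTANT_ORDER = ("gyr1", "gyr2", "acc1", "acc2", "mag1", "mag2")

DEFAULT_BAND = (1.0, 16.0)
_FILTER_ORDER = 4


@dataclass
class ResultantSignal:
    """Scalar magnitude series of one sensor, optionally mean-detrended."""

    sensor_name: str
    samples: np.ndarray
    sampling_rate: float
    detrended: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ShapeError("resultant samples must be 1-D")


def bandpass(
    x: np.ndarray,
    rate: float,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass, same length as input."""
    x = np.asarray(x, dtype=float)
    nyquist = rate / 2.0
    if high >= nyquist:
        raise ConfigurationError(
            f"high cutoff {high} Hz must be below Nyquist {nyquist} Hz"
        )
    if not 0 < low < high:
        raise ConfigurationError("need 0 < low < high")
    sos = sps.butter(_FILTER_ORDER, [low, high], btype="bandpass", fs=rate, output="sos")
    if x.shape[-1] < 24:  # sosfiltfilt needs enough samples to pad
        raise ShapeError(f"signal too short to filter (n={x.shape[-1]})")
    return sps.sosfiltfilt(sos, x, axis=-1)


def resultant(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-sample magnitude sqrt(x^2 + y^2 + z^2)."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ShapeError(
            f"axis length mismatch: {x.shape}, {y.shape}, {z.shape}"
        )
    return np.sqrt(x * x + y * y + z * z)


def detrend_mean(x: np.ndarray) -> np.ndarray:
    """Subtract the mean; output mean is 0 to floating precision."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ShapeError("cannot detrend an empty signal")
    return x - x.mean()


def preprocess_recording(
    rec: IMURecording, band: tuple[float, float] = DEFAULT_BAND
) -> list[ResultantSignal]:
    """Band-pass each axis, form the resultant, detrend; one signal per sensor.

    Output order is fixed: gyr1, gyr2, acc1, acc2, mag1, mag2.
    """
    low, high = band
    out = []
    for name in RESULTANT_ORDER:
        axes = rec.series[name]
        filtered = bandpass(axes.T, rec.sampling_rate, low, high)
        r = resultant(filtered[0], filtered[1], filtered[2])
        out.append(
            ResultantSignal(
                sensor_name=name,
                samples=detrend_mean(r),
                sampling_rate=rec.sampling_rate,
                detrended=True,
            )
        )
    return out
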