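"""Synthetic two-IMU resting-hand cohorts.

Generates recordings with the statistical structure the downstream
analysis assumes: PD-like subjects carry an amplitude-modulated
oscillation inside the 3.5-7.5 Hz band projected onto the three axes
of each sensor, on top of independent Gaussian noise; healthy-like
subjects carry noise only.  Severity is encoded through an HY-style
score: score-1 subjects get sub-noise-floor amplitudes, score-2
subjects get clearly visible ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError
from .recording import IMURecording, read_recording, write_recording  # noqa: F401

TREMOR_BAND = (3.5, 7.5)

#: Oscillation gain per sensor kind relative to the accelerometer.
_SENSOR_GAIN = {"acc": 1.0, "gyr": 1.0, "mag": 0.2}
#: Forearm IMU sees an attenuated version of the hand oscillation.
_IMU_GAIN = {1: 1.0, 2: 0.6}
_GRAVITY_OFFSET = 9.81  # constant added to each accelerometer z axis


@dataclass
class SubjectSpec:
    """Ground-truth generative parameters of one simulated subject."""

    subject_id: str
    group: str  # "PD" | "healthy"
    hy_score: int  # 0 for healthy, 1 or 2 for PD
    tremor_freq: float  # Hz, inside TREMOR_BAND
    tremor_amp: float  # multiple of the per-axis noise SD
    n_trials: int = 3


@dataclass
class CohortConfig:
    n_pd: int = 15
    n_healthy: int = 12
    n_hy1: int = 11
    sampling_rate: float = 50.0
    trial_duration: float = 15.0
    n_trials: int = 3
    seed: int = 0
    noise_sd: float = 1.0
    hy1_amp_range: tuple[float, float] = (0.2, 0.6)
    hy2_amp_range: tuple[float, float] = (2.0, 5.0)

    def validate(self) -> None:
        if self.n_pd < 0 or self.n_healthy < 0:
            raise ConfigurationError("subject counts must be non-negative")
        if self.n_pd + self.n_healthy < 1:
            raise ConfigurationError("cohort must contain at least one subject")
        if self.n_hy1 < 0 or self.n_hy1 > self.n_pd:
            raise ConfigurationError("need 0 <= n_hy1 <= n_pd")
        if self.sampling_rate <= 0 or self.trial_duration <= 0:
            raise ConfigurationError("sampling rate and duration must be positive")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be positive")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        n = self.sampling_rate * self.trial_duration
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"rate x duration = {n} is not an integer sample count"
            )
        for lo, hi in (self.hy1_amp_range, self.hy2_amp_range):
            if lo < 0 or hi < lo:
                raise ConfigurationError("amplitude ranges must satisfy 0 <= lo <= hi")
        if self.hy1_amp_range[1] > self.hy2_amp_range[0] and self.hy2_amp_range[0] > 0:
            raise ConfigurationError(
                "HY=1 amplitudes must not exceed the HY=2 minimum"
            )

    @property
    def n_samples(self) -> int:
        return round(self.sampling_rate * self.trial_duration)


def _slow_envelope(rng: np.random.Generator, n: int, rate: float) -> np.ndarray:
    """Positive, slowly varying modulation with mean ~1 (low-passed noise)."""
    raw = rng.standard_normal(n + 200)
    sos = sps.butter(2, min(0.5, 0.45 * rate) / (rate / 2), btype="low", output="sos")
    slow = sps.sosfiltfilt(sos, raw)[100 : 100 + n]
    sd = slow.std()
    if sd > 0:
        slow = slow / sd
    env = np.clip(1.0 + 0.3 * slow, 0.1, None)
    return env / env.mean()


def _draw_subjects(config: CohortConfig, rng: np.random.Generator) -> list[SubjectSpec]:
    subjects = []
    for i in range(config.n_pd):
        hy = 1 if i < config.n_hy1 else 2
        lo, hi = config.hy1_amp_range if hy == 1 else config.hy2_amp_range
        subjects.append(
            SubjectSpec(
                subject_id=f"pd{i + 1:02d}",
                group="PD",
                hy_score=hy,
                tremor_freq=float(rng.uniform(*TREMOR_BAND)),
                tremor_amp=float(rng.uniform(lo, hi)),
                n_trials=config.n_trials,
            )
        )
    for i in range(config.n_healthy):
        subjects.append(
            SubjectSpec(
                subject_id=f"hc{i + 1:02d}",
                group="healthy",
                hy_score=0,
                tremor_freq=float(rng.uniform(*TREMOR_BAND)),  # unused (amp 0)
                tremor_amp=0.0,
                n_trials=config.n_trials,
            )
        )
    return subjects


def _simulate_trial(
    spec: SubjectSpec,
    config: CohortConfig,
    directions: dict[int, np.ndarray],
    rng: np.random.Generator,
    trial: int,
) -> IMURecording:
    n = config.n_samples
    rate = config.sampling_rate
    t = np.arange(n) / rate
    phase = rng.uniform(0, 2 * np.pi)
    if spec.tremor_amp > 0:
        env = _slow_envelope(rng, n, rate)
        osc = (
            spec.tremor_amp
            * config.noise_sd
            * env
            * np.sin(2 * np.pi * spec.tremor_freq * t + phase)
        )
    else:
        osc = np.zeros(n)
    series = {}
    for imu in (1, 2):
        u = directions[imu]
        kinematic = np.outer(osc * _IMU_GAIN[imu], u)  # (n, 3)
        for kind in ("acc", "gyr", "mag"):
            noise = rng.normal(0.0, config.noise_sd, size=(n, 3))
            axes = kinematic * _SENSOR_GAIN[kind] + noise
            if kind == "acc":
                axes[:, 2] += _GRAVITY_OFFSET
            series[f"{kind}{imu}"] = axes
    return IMURecording(
        sampling_rate=rate,
        series=series,
        subject_id=spec.subject_id,
        trial=trial,
        group=spec.group,
        hy_score=spec.hy_score,
    )


def generate_cohort(
    config: CohortConfig,
) -> list[tuple[SubjectSpec, list[IMURecording]]]:
    """Simulate a full cohort; identical config+seed gives identical output.

    Returns one ``(SubjectSpec, [IMURecording, ...])`` pair per subject,
    PD subjects first.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    subjects = _draw_subjects(config, rng)
    cohort = []
    for spec in subjects:
        u = rng.standard_normal(3)
        directions = {1: u / np.linalg.norm(u)}
        v = rng.standard_normal(3)
        directions[2] = v / np.linalg.norm(v)
        trials = [
            _simulate_trial(spec, config, directions, rng, trial=k + 1)
            for k in range(spec.n_trials)
        ]
        cohort.append((spec, trials))
    return cohort
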