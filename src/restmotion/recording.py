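"""Two-IMU recording container and its plain-text serialization.

A recording holds six triaxial sensor streams (hand IMU and forearm IMU,
each with accelerometer, gyroscope, magnetometer) sampled at a common
rate, plus subject metadata.

Text dialect: UTF-8 CSV with one metadata comment line
``# rate_hz=<r> subject=<id> trial=<k> group=<PD|healthy> hy=<n>``,
a header ``time,acc1_x,...,mag2_z`` (19 columns), then one row per sample.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import ParseError, ShapeError

#: Canonical sensor names: IMU 1 is on the hand, IMU 2 on the forearm.
SENSOR_NAMES = ("acc1", "gyr1", "mag1", "acc2", "gyr2", "mag2")

AXES = ("x", "y", "z")

_COLUMNS = ["time"] + [f"{s}_{a}" for s in SENSOR_NAMES for a in AXES]


@dataclass
class IMURecording:
    """One subject-trial: 6 sensors x 3 axes x N samples plus metadata."""

    sampling_rate: float
    series: dict[str, np.ndarray]  # sensor name -> (N, 3) array
    subject_id: str = ""
    trial: int = 0
    group: str = "healthy"  # "PD" | "healthy"
    hy_score: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ShapeError("sampling_rate must be positive")
        if set(self.series) != set(SENSOR_NAMES):
            raise ShapeError(
                f"sensor names must be exactly {set(SENSOR_NAMES)}, "
                f"got {set(self.series)}"
            )
        lengths = set()
        for name in SENSOR_NAMES:
            arr = np.asarray(self.series[name], dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ShapeError(f"sensor {name!r} must be an (N, 3) array")
            self.series[name] = arr
            lengths.add(arr.shape[0])
        if len(lengths) != 1:
            raise ShapeError(f"axis series have unequal lengths: {sorted(lengths)}")
        n = lengths.pop()
        if n < 2:
            raise ShapeError("recordings need at least 2 samples")

    @property
    def n_samples(self) -> int:
        return self.series[SENSOR_NAMES[0]].shape[0]

    @property
    def duration(self) -> float:
        """Trial duration in seconds (n / rate)."""
        return self.n_samples / self.sampling_rate


def write_recording(rec: IMURecording, path: str | os.PathLike) -> str:
    """Write ``rec`` to ``path`` in the CSV dialect; returns the path."""
    n = rec.n_samples
    t = np.arange(n) / rec.sampling_rate
    data = np.column_stack([t] + [rec.series[s] for s in SENSOR_NAMES])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# rate_hz={rec.sampling_rate:g} subject={rec.subject_id} "
            f"trial={rec.trial} group={rec.group} hy={rec.hy_score}\n"
        )
        fh.write(",".join(_COLUMNS) + "\n")
        for row in data:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")
    return os.fspath(path)


def _parse_meta(line: str, path: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    for token in line.lstrip("#").split():
        if "=" not in token:
            raise ParseError(f"{path}:1: malformed metadata token {token!r}")
        key, _, value = token.partition("=")
        meta[key] = value
    for key in ("rate_hz", "subject", "trial", "group", "hy"):
        if key not in meta:
            raise ParseError(f"{path}:1: metadata missing {key!r}")
    return meta


def read_recording(path: str | os.PathLike) -> IMURecording:
    """Read a recording written by :func:`write_recording`.

    Raises :class:`ParseError` naming the line number on malformed
    headers, ragged rows, or non-numeric cells.
    """
    path = os.fspath(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}:1: file too short to be a recording")
    if not lines[0].startswith("#"):
        raise ParseError(f"{path}:1: missing metadata comment line")
    meta = _parse_meta(lines[0], path)
    header = lines[1].split(",")
    if header != _COLUMNS:
        raise ParseError(
            f"{path}:2: header mismatch; expected {len(_COLUMNS)} columns "
            f"{','.join(_COLUMNS[:4])},..., got {len(header)}"
        )
    rows = []
    for i, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != len(_COLUMNS):
            raise ParseError(
                f"{path}:{i}: expected {len(_COLUMNS)} cells, got {len(cells)}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: non-numeric cell ({exc})") from None
    data = np.asarray(rows, dtype=float)
    series = {
        s: data[:, 1 + 3 * k : 4 + 3 * k] for k, s in enumerate(SENSOR_NAMES)
    }
    return IMURecording(
        sampling_rate=float(meta["rate_hz"]),
        series=series,
        subject_id=meta["subject"],
        trial=int(meta["trial"]),
        group=meta["group"],
        hy_score=int(meta["hy"]),
    )
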