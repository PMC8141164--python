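"""Experiment configuration: one YAML document, one master seed."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .classification import ClassifierSpec
from .errors import ConfigurationError
from .features import EntropyParams
from .selection import PERCENT_GRID
from .synthetic import CohortConfig


def substream_seed(seed: int, name: str) -> int:
    """Derive a named, reproducible child seed from the master seed."""
    ss = np.random.SeedSequence([seed, zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0])


@dataclass
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    entropy: EntropyParams = field(default_factory=EntropyParams)
    band: tuple[float, float] = (1.0, 16.0)
    classifiers: tuple[str, ...] = ("KNN", "SVM", "RF", "NB")
    percentages: tuple[int, ...] = PERCENT_GRID
    folds: int = 10
    train_fraction: float = 0.5
    relieff_k: int = 1
    aggregate: str = "mean"
    spectrum_estimator: str = "periodogram"
    rank_on: str = "train"
    seed: int = 0
    out_dir: str = "results"

    def validate(self) -> None:
        self.cohort.validate()
        self.entropy.validate()
        low, high = self.band
        if not 0 < low < high:
            raise ConfigurationError("band must satisfy 0 < low < high")
        if high >= self.cohort.sampling_rate / 2:
            raise ConfigurationError(
                f"band high {high} Hz must be below Nyquist "
                f"{self.cohort.sampling_rate / 2} Hz"
            )
        if set(self.percentages) - set(PERCENT_GRID):
            raise ConfigurationError("percentages must lie on the 10..100 grid")

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(self.band)
        d["classifiers"] = list(self.classifiers)
        d["percentages"] = list(self.percentages)
        d["cohort"]["hy1_amp_range"] = list(self.cohort.hy1_amp_range)
        d["cohort"]["hy2_amp_range"] = list(self.cohort.hy2_amp_range)
        return d

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in data:
            cdata = dict(data["cohort"])
            cunknown = set(cdata) - set(CohortConfig.__dataclass_fields__)
            if cunknown:
                raise ConfigurationError(f"unknown cohort keys: {sorted(cunknown)}")
            for key in ("hy1_amp_range", "hy2_amp_range"):
                if key in cdata:
                    cdata[key] = tuple(cdata[key])
            data["cohort"] = CohortConfig(**cdata)
        if "entropy" in data:
            edata = dict(data["entropy"])
            eunknown = set(edata) - set(EntropyParams.__dataclass_fields__)
            if eunknown:
                raise ConfigurationError(f"unknown entropy keys: {sorted(eunknown)}")
            data["entropy"] = EntropyParams(**edata)
        for key in ("band", "classifiers", "percentages"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def classifier_specs(self) -> list[ClassifierSpec]:
        return [
            ClassifierSpec(kind=k, seed=substream_seed(self.seed, f"rf:{k}"))
            for k in self.classifiers
        ]
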