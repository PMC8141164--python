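"""Z-score normalization and ReliefF-based percentage feature subsets."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, RankingError
from .features import feature_columns

PERCENT_GRID = tuple(range(10, 101, 10))


@dataclass
class RankedFeatures:
    """ReliefF weights plus the descending-weight feature order.

    Ties are broken by original column index (stable sort), which makes
    the ranking deterministic and row-order independent.
    """

    scores: dict[str, float]
    order: list[str]


@dataclass
class ZScoreScaler:
    """Column-wise (value - mean) / sd with the n-1 SD, fit on one table.

    Constant columns (sd == 0) are flagged and dropped at transform time
    so they cannot silently corrupt ranking or classification.
    """

    means: pd.Series | None = None
    sds: pd.Series | None = None
    columns: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    def fit(self, table: pd.DataFrame) -> "ZScoreScaler":
        cols = feature_columns(table)
        mu = table[cols].mean()
        sd = table[cols].std(ddof=1)
        self.dropped = [c for c in cols if not sd[c] > 0]
        if self.dropped:
            warnings.warn(
                f"dropping {len(self.dropped)} constant feature column(s): "
                f"{self.dropped[:5]}...",
                stacklevel=2,
            )
        self.columns = [c for c in cols if c not in self.dropped]
        self.means = mu[self.columns]
        self.sds = sd[self.columns]
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.means is None:
            raise ConfigurationError("scaler not fitted")
        meta = [c for c in table.columns if c not in feature_columns(table)]
        scaled = (table[self.columns] - self.means) / self.sds
        return pd.concat([table[meta], scaled], axis=1)


def zscore_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize each feature column of a table to mean 0, SD 1 (ddof=1)."""
    return ZScoreScaler().fit(table).transform(table)


def _min_max_scale(x: np.ndarray) -> np.ndarray:
    lo = x.min(axis=0)
    span = x.max(axis=0) - lo
    span_safe = np.where(span > 0, span, 1.0)
    scaled = (x - lo) / span_safe
    scaled[:, span == 0] = 0.0
    return scaled


def relieff_rank(
    table: pd.DataFrame, k: int = 1, n_iterations: int | None = None
) -> RankedFeatures:
    """Deterministic ReliefF weights over all instances.

    For each instance the k nearest hits (same class) and k nearest
    misses (other class) are found with Manhattan distance on min-max
    scaled features; each feature's weight accumulates the mean scaled
    miss difference minus the mean scaled hit difference.
    """
    cols = feature_columns(table)
    x = table[cols].to_numpy(dtype=float)
    labels = table["label"].to_numpy()
    if x.shape[0] < 2:
        raise RankingError("need at least two rows to rank features")
    if np.isnan(x).any():
        raise RankingError("feature table contains missing values")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise RankingError("both classes must be present for ranking")
    if k >= counts.min():
        raise RankingError(
            f"k={k} needs every class to have more than k members "
            f"(smallest class has {counts.min()})"
        )
    scaled = _min_max_scale(x)
    n = x.shape[0]
    iters = n if n_iterations is None else min(n_iterations, n)
    weights = np.zeros(len(cols))
    for i in range(iters):
        diffs = np.abs(scaled - scaled[i])  # (n, p) per-feature scaled diffs
        dist = diffs.sum(axis=1)
        same = labels == labels[i]
        hit_idx = np.flatnonzero(same)
        hit_idx = hit_idx[hit_idx != i]
        miss_idx = np.flatnonzero(~same)
        # argsort is stable: equal distances resolve to the lowest index
        nearest_hits = hit_idx[np.argsort(dist[hit_idx], kind="stable")[:k]]
        nearest_misses = miss_idx[np.argsort(dist[miss_idx], kind="stable")[:k]]
        weights += (
            diffs[nearest_misses].mean(axis=0) - diffs[nearest_hits].mean(axis=0)
        ) / iters
    order_idx = np.argsort(-weights, kind="stable")
    return RankedFeatures(
        scores=dict(zip(cols, weights)),
        order=[cols[j] for j in order_idx],
    )


def percent_subset(
    ranked: RankedFeatures, pct: int, total: int | None = None
) -> list[str]:
    """Top round-half-up(pct% of total) feature names from a ranking."""
    if pct not in PERCENT_GRID:
        raise ConfigurationError(f"pct must be one of {PERCENT_GRID}, got {pct}")
    if total is None:
        total = len(ranked.order)
    count = math.floor(pct * total / 100.0 + 0.5)
    return ranked.order[:count]
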