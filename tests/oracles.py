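"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately written as plain loops, separate from the
package's vectorized code paths.
"""

import math
from fractions import Fraction

import numpy as np


def apen_oracle(x, m=2, r_mult=0.2):
    """O(N^2) approximate entropy: Chebyshev distance, self-matches in."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    r = r_mult * float(np.std(x))

    def phi(mm):
        nv = n - mm + 1
        vecs = [x[i : i + mm] for i in range(nv)]
        total = 0.0
        for i in range(nv):
            count = 0
            for j in range(nv):
                if np.max(np.abs(vecs[i] - vecs[j])) <= r:
                    count += 1
            total += math.log(count / nv)
        return total / nv

    return phi(m) - phi(m + 1)


def fuzzyen_oracle(x, m=2, r_mult=0.2, power=2):
    """O(N^2) fuzzy entropy: baseline-removed vectors, exp(-(d/r)^p),
    self-matches excluded, both lengths indexed 1..N-m."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    r = r_mult * float(np.std(x))
    nv = n - m

    def phi(mm):
        vecs = [x[i : i + mm] - np.mean(x[i : i + mm]) for i in range(nv)]
        total = 0.0
        for i in range(nv):
            s = 0.0
            for j in range(nv):
                if j == i:
                    continue
                d = np.max(np.abs(vecs[i] - vecs[j]))
                s += math.exp(-((d / r) ** power))
            total += s / (nv - 1)
        return total / nv

    return math.log(phi(m)) - math.log(phi(m + 1))


def relieff_oracle(x, labels, k=1):
    """Brute-force ReliefF over all instances: min-max scaling, Manhattan
    distance, k nearest hits/misses (stable ties), scaled feature diffs."""
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    lo = x.min(axis=0)
    span = x.max(axis=0) - lo
    scaled = np.zeros_like(x)
    for j in range(p):
        if span[j] > 0:
            scaled[:, j] = (x[:, j] - lo[j]) / span[j]
    weights = np.zeros(p)
    for i in range(n):
        dists = [(np.sum(np.abs(scaled[j] - scaled[i])), j) for j in range(n)]
        hits = sorted(d for d in dists if labels[d[1]] == labels[i] and d[1] != i)
        misses = sorted(d for d in dists if labels[d[1]] != labels[i])
        for f in range(p):
            miss_diff = np.mean(
                [abs(scaled[j][f] - scaled[i][f]) for _, j in misses[:k]]
            )
            hit_diff = np.mean(
                [abs(scaled[j][f] - scaled[i][f]) for _, j in hits[:k]]
            )
            weights[f] += (miss_diff - hit_diff) / n
    return weights


def metric_fractions(tp, fp, tn, fn):
    """Exact confusion-matrix metrics as Fractions (None when undefined)."""

    def frac(num, den):
        return Fraction(num, den) if den > 0 else None

    return {
        "sensitivity": frac(tp, tp + fn),
        "specificity": frac(tn, tn + fp),
        "precision": frac(tp, tp + fp),
        "accuracy": frac(tp + tn, tp + fp + tn + fn),
    }
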