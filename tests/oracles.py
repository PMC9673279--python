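"""Independent brute-force oracles used by the test suite.

Everything here is written as literal, loop-based transcriptions of the
defining formulas, deliberately independent of the vectorised
implementations in :mod:`tmjoa` that they check.
"""

from __future__ import annotations

import math

import numpy as np


def glcm_oracle(binned: np.ndarray, radius: int, n_bins: int) -> np.ndarray:
    """Co-occurrence counts by a double loop over all ordered voxel pairs."""
    counts = np.zeros((n_bins, n_bins), dtype=np.int64)
    voxels = list(np.ndindex(binned.shape))
    for a in voxels:
        for b in voxels:
            if a == b:
                continue
            if max(abs(a[0] - b[0]), abs(a[1] - b[1]), abs(a[2] - b[2])) <= radius:
                counts[binned[a] - 1, binned[b] - 1] += 1
    return counts


def glcm_features_oracle(p: np.ndarray) -> dict[str, float]:
    """Literal-formula Haralick features from a normalised matrix."""
    nb = p.shape[0]
    energy = sum(p[i, j] ** 2 for i in range(nb) for j in range(nb))
    entropy = -sum(
        p[i, j] * math.log2(p[i, j])
        for i in range(nb)
        for j in range(nb)
        if p[i, j] > 0
    )
    inertia = sum(
        (i - j) ** 2 * p[i - 1, j - 1]
        for i in range(1, nb + 1)
        for j in range(1, nb + 1)
    )
    idm = sum(
        p[i - 1, j - 1] / (1 + (i - j) ** 2)
        for i in range(1, nb + 1)
        for j in range(1, nb + 1)
    )
    px = [sum(p[i, j] for j in range(nb)) for i in range(nb)]
    mu = sum((i + 1) * px[i] for i in range(nb))
    var = sum((i + 1 - mu) ** 2 * px[i] for i in range(nb))
    shade = sum(
        (i + j - 2 * mu) ** 3 * p[i - 1, j - 1]
        for i in range(1, nb + 1)
        for j in range(1, nb + 1)
    )
    prom = sum(
        (i + j - 2 * mu) ** 4 * p[i - 1, j - 1]
        for i in range(1, nb + 1)
        for j in range(1, nb + 1)
    )
    if var > 0:
        corr = (
            sum(
                (i - mu) * (j - mu) * p[i - 1, j - 1]
                for i in range(1, nb + 1)
                for j in range(1, nb + 1)
            )
            / var
        )
        har = (
            sum(
                i * j * p[i - 1, j - 1]
                for i in range(1, nb + 1)
                for j in range(1, nb + 1)
            )
            - mu**2
        ) / var
    else:
        corr = 0.0
        har = 0.0
    return {
        "Energy": energy,
        "Entropy": entropy,
        "Correlation": corr,
        "InverseDifferenceMoment": idm,
        "Inertia": inertia,
        "ClusterShade": shade,
        "ClusterProminence": prom,
        "HaralickCorrelation": har,
    }


def glrlm_oracle(
    binned: np.ndarray, directions, n_bins: int, max_len: int
) -> np.ndarray:
    """Run counts by explicit line walking and run splitting."""
    counts = np.zeros((n_bins, max_len), dtype=np.int64)
    shape = binned.shape
    inside = lambda p: all(0 <= p[k] < shape[k] for k in range(3))
    for d in directions:
        for start in np.ndindex(shape):
            prev = (start[0] - d[0], start[1] - d[1], start[2] - d[2])
            if inside(prev):
                continue  # not a line start
            line = []
            pos = start
            while inside(pos):
                line.append(binned[pos])
                pos = (pos[0] + d[0], pos[1] + d[1], pos[2] + d[2])
            k = 0
            while k < len(line):
                j = k
                while j < len(line) and line[j] == line[k]:
                    j += 1
                counts[line[k] - 1, j - k - 1] += 1
                k = j
    return counts


def glrlm_features_oracle(counts: np.ndarray) -> dict[str, float]:
    """Literal-formula run-length features."""
    nb, ml = counts.shape
    nr = counts.sum()
    feats = {k: 0.0 for k in (
        "ShortRunEmphasis", "LongRunEmphasis", "LowGreyLevelRunEmphasis",
        "HighGreyLevelRunEmphasis", "ShortRunLowGreyLevelRunEmphasis",
        "ShortRunHighGreyLevelRunEmphasis", "LongRunLowGreyLevelRunEmphasis",
        "LongRunHighGreyLevelRunEmphasis")}
    for i in range(1, nb + 1):
        for r in range(1, ml + 1):
            c = counts[i - 1, r - 1]
            if c == 0:
                continue
            feats["ShortRunEmphasis"] += c / r**2
            feats["LongRunEmphasis"] += c * r**2
            feats["LowGreyLevelRunEmphasis"] += c / i**2
            feats["HighGreyLevelRunEmphasis"] += c * i**2
            feats["ShortRunLowGreyLevelRunEmphasis"] += c / (i**2 * r**2)
            feats["ShortRunHighGreyLevelRunEmphasis"] += c * i**2 / r**2
            feats["LongRunLowGreyLevelRunEmphasis"] += c * r**2 / i**2
            feats["LongRunHighGreyLevelRunEmphasis"] += c * i**2 * r**2
    out = {k: v / nr for k, v in feats.items()}
    out["GreyLevelNonUniformity"] = sum(
        counts[i].sum() ** 2 for i in range(nb)
    ) / nr
    out["RunLengthNonUniformity"] = sum(
        counts[:, r].sum() ** 2 for r in range(ml)
    ) / nr
    return out


def auc_oracle(x1, x0) -> float:
    """Fraction of (diseased, control) pairs won, ties counted one half."""
    wins = sum(1.0 * (a > b) + 0.5 * (a == b) for a in x1 for b in x0)
    return wins / (len(x1) * len(x0))


def best_stump_oracle(x: np.ndarray, g: np.ndarray, h: np.ndarray,
                      lam: float, min_leaf: int = 1):
    """Exhaustive best split of a single feature by literal gain formula.

    Returns (threshold, gain) or None.
    """
    vals = np.unique(x)
    best = None
    G, H = g.sum(), h.sum()
    parent = G * G / (H + lam)
    for a, b in zip(vals[:-1], vals[1:]):
        thr = 0.5 * (a + b)
        left = x < thr
        if left.sum() < min_leaf or (~left).sum() < min_leaf:
            continue
        GL, HL = g[left].sum(), h[left].sum()
        GR, HR = G - GL, H - HL
        gain = 0.5 * (GL**2 / (HL + lam) + GR**2 / (HR + lam) - parent)
        if best is None or gain > best[1] + 1e-12:
            best = (thr, gain)
    return best
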