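"""Grey-level co-occurrence (GLCM) and run-length (GLRLM) texture features.

The 18 texture biomarkers computed here are the classic Haralick (GLCM)
and Galloway/Chu (GLRLM) statistics used for subchondral-bone texture in
high-resolution CBCT.  Conventions, fixed once and used everywhere:

* Intensities are quantised into ``n_bins`` equal-width bins spanning
  ``[intensity_min, intensity_max]`` (defaults 10 bins over [-1000, 2500]);
  values outside the range are clipped.  Bin indices are 1-based in every
  formula.
* The co-occurrence matrix pools ordered voxel pairs over *all* offsets
  within Chebyshev distance ``neighborhood_radius`` (default 4) into a
  single matrix, which is therefore symmetric by construction.
* The run-length matrix counts maximal same-bin runs with unit step along
  the 13 unique 3D directions, pooled into one matrix.
* Entropy uses log base 2.  On a constant image the grey-level variance is
  zero, so Correlation and HaralickCorrelation are returned as 0.0 with a
  ``degenerate`` flag instead of NaN, keeping feature tables numeric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Canonical order of the 8 GLCM feature names.
GLCM_FEATURES = (
    "Energy",
    "Entropy",
    "Correlation",
    "InverseDifferenceMoment",
    "Inertia",
    "ClusterShade",
    "ClusterProminence",
    "HaralickCorrelation",
)

#: Canonical order of the 10 GLRLM feature names.
GLRLM_FEATURES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GreyLevelNonUniformity",
    "RunLengthNonUniformity",
    "LowGreyLevelRunEmphasis",
    "HighGreyLevelRunEmphasis",
    "ShortRunLowGreyLevelRunEmphasis",
    "ShortRunHighGreyLevelRunEmphasis",
    "LongRunLowGreyLevelRunEmphasis",
    "LongRunHighGreyLevelRunEmphasis",
)

TEXTURE_FEATURES = GLCM_FEATURES + GLRLM_FEATURES

#: The 13 unique (up to sign) unit-step directions of a 3D grid.
DIRECTIONS_13 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)


@dataclass(frozen=True)
class TextureParams:
    """Quantisation and neighbourhood parameters for texture extraction."""

    n_bins: int = 10
    intensity_min: float = -1000.0
    intensity_max: float = 2500.0
    neighborhood_radius: int = 4
    run_distance_min: int = 0
    run_distance_max: int = 1
    inside_mask_value: int = 1

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.intensity_min >= self.intensity_max:
            raise ValueError("intensity_min must be < intensity_max")
        if self.neighborhood_radius < 1:
            raise ValueError("neighborhood_radius must be >= 1")


@dataclass
class CooccurrenceMatrix:
    """Symmetric pooled grey-level co-occurrence matrix.

    ``counts[i-1, j-1]`` is the number of ordered voxel pairs (a, b) with
    ``0 < chebyshev(a, b) <= radius``, ``bin(a) = i`` and ``bin(b) = j``.
    ``p`` is the normalised copy summing to 1.
    """

    counts: np.ndarray
    radius: int

    @property
    def p(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("empty co-occurrence matrix")
        return self.counts / total


@dataclass
class RunLengthMatrix:
    """Pooled grey-level run-length matrix.

    ``counts[i-1, r-1]`` is the number of maximal runs of bin ``i`` with
    length ``r``, pooled over the direction set.  ``n_voxels`` is the voxel
    count of the source block and ``n_directions`` the number of directions
    pooled, so ``sum(counts * r) == n_voxels * n_directions``.
    """

    counts: np.ndarray
    n_voxels: int
    n_directions: int

    @property
    def n_runs(self) -> int:
        return int(self.counts.sum())


def quantize(block: np.ndarray, params: TextureParams = TextureParams()) -> np.ndarray:
    """Quantise intensities into 1-based equal-width bins with clipping.

    ``intensity_min`` maps to bin 1 and ``intensity_max`` to bin ``n_bins``
    (the top edge is inclusive); out-of-range values are clipped into the
    range, which is the documented contract rather than an error.
    """
    arr = np.asarray(block, dtype=float)
    lo, hi = params.intensity_min, params.intensity_max
    width = (hi - lo) / params.n_bins
    idx = np.floor((np.clip(arr, lo, hi) - lo) / width).astype(np.int64) + 1
    return np.clip(idx, 1, params.n_bins)


def build_glcm(
    binned: np.ndarray, params: TextureParams = TextureParams()
) -> CooccurrenceMatrix:
    """Accumulate the pooled co-occurrence matrix of a binned block.

    Every ordered voxel pair within Chebyshev distance ``radius`` is counted
    once, which symmetrises the matrix (each unordered pair contributes to
    both (i, j) and (j, i)).
    """
    binned = np.asarray(binned)
    if binned.size == 0:
        raise ValueError("empty block")
    if binned.ndim != 3:
        raise ValueError("expected a 3D binned block")
    r = params.neighborhood_radius
    nb = params.n_bins
    counts = np.zeros((nb, nb), dtype=np.int64)
    offsets = [
        (dx, dy, dz)
        for dx in range(-r, r + 1)
        for dy in range(-r, r + 1)
        for dz in range(-r, r + 1)
        if (dx, dy, dz) > (0, 0, 0)
    ]
    nx, ny, nz = binned.shape

    def _slices(d: int, n: int) -> tuple[slice, slice]:
        if d >= 0:
            return slice(0, n - d), slice(d, n)
        return slice(-d, n), slice(0, n + d)

    for dx, dy, dz in offsets:
        if abs(dx) >= nx or abs(dy) >= ny or abs(dz) >= nz:
            continue
        ax, bx = _slices(dx, nx)
        ay, by = _slices(dy, ny)
        az, bz = _slices(dz, nz)
        a = binned[ax, ay, az].ravel()
        b = binned[bx, by, bz].ravel()
        np.add.at(counts, (a - 1, b - 1), 1)
    # Counting each half-space offset once and mirroring gives the ordered-
    # pair (symmetric) matrix.
    counts = counts + counts.T
    return CooccurrenceMatrix(counts=counts, radius=r)


def glcm_features(matrix: CooccurrenceMatrix) -> dict[str, float]:
    """The 8 Haralick-style features of a normalised co-occurrence matrix.

    Returns a dict in :data:`GLCM_FEATURES` order plus a ``degenerate``
    flag that is True when the grey-level variance is zero (constant image),
    in which case Correlation and HaralickCorrelation are 0 by convention.
    """
    p = matrix.p
    nb = p.shape[0]
    i = np.arange(1, nb + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    energy = float(np.sum(p**2))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    inertia = float(np.sum((ii - jj) ** 2 * p))
    idm = float(np.sum(p / (1.0 + (ii - jj) ** 2)))

    # Marginal of the symmetric matrix (identical on rows and columns).
    px = p.sum(axis=1)
    mu = float(np.sum(i * px))
    var = float(np.sum((i - mu) ** 2 * px))
    shade = float(np.sum((ii + jj - 2 * mu) ** 3 * p))
    prominence = float(np.sum((ii + jj - 2 * mu) ** 4 * p))

    degenerate = var <= 0
    if degenerate:
        correlation = 0.0
        haralick = 0.0
    else:
        correlation = float(np.sum((ii - mu) * (jj - mu) * p) / var)
        haralick = float((np.sum(ii * jj * p) - mu**2) / var)

    return {
        "Energy": energy,
        "Entropy": entropy,
        "Correlation": correlation,
        "InverseDifferenceMoment": idm,
        "Inertia": inertia,
        "ClusterShade": shade,
        "ClusterProminence": prominence,
        "HaralickCorrelation": haralick,
        "degenerate": degenerate,
    }


def _iter_lines(shape: tuple[int, int, int], direction: tuple[int, int, int]):
    """Yield index arrays for every maximal lattice line along a direction."""
    nx, ny, nz = shape
    dx, dy, dz = direction
    sizes = (nx, ny, nz)
    # Starting voxels: those whose predecessor along the direction is outside.
    grids = np.indices(shape).reshape(3, -1)
    prev = grids - np.array([[dx], [dy], [dz]])
    outside = (
        (prev[0] < 0)
        | (prev[0] >= nx)
        | (prev[1] < 0)
        | (prev[1] >= ny)
        | (prev[2] < 0)
        | (prev[2] >= nz)
    )
    starts = grids[:, outside].T
    for sx, sy, sz in starts:
        # Steps available before leaving the grid on any moving axis.
        length = min(
            (s if d < 0 else (n - 1 - s)) // abs(d) if d != 0 else np.inf
            for s, d, n in zip((sx, sy, sz), (dx, dy, dz), sizes)
        )
        t = np.arange(int(length) + 1)
        yield sx + t * dx, sy + t * dy, sz + t * dz


def _run_length_encode(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Values and lengths of maximal constant runs in a 1D array."""
    if values.size == 0:
        return values, np.empty(0, dtype=np.int64)
    change = np.flatnonzero(np.diff(values) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [values.size]))
    return values[starts], ends - starts


def build_glrlm(
    binned: np.ndarray,
    params: TextureParams = TextureParams(),
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> RunLengthMatrix:
    """Count maximal same-bin runs along each direction, pooled.

    Runs use unit steps (the distance-range [0, 1] convention) and are
    maximal within the block; each voxel belongs to exactly one run per
    direction.
    """
    binned = np.asarray(binned)
    if binned.size == 0:
        raise ValueError("empty block")
    if binned.ndim != 3:
        raise ValueError("expected a 3D binned block")
    nb = params.n_bins
    max_len = max(binned.shape) if len(directions) else 1
    # Diagonal lines can be at most min over moving axes, but max(shape)
    # is a safe upper bound for any direction.
    counts = np.zeros((nb, max_len), dtype=np.int64)
    for d in directions:
        for xs, ys, zs in _iter_lines(binned.shape, d):
            vals, lengths = _run_length_encode(binned[xs, ys, zs])
            np.add.at(counts, (vals - 1, lengths - 1), 1)
    return RunLengthMatrix(
        counts=counts, n_voxels=int(binned.size), n_directions=len(directions)
    )


def glrlm_features(matrix: RunLengthMatrix) -> dict[str, float]:
    """The 10 Galloway/Chu run-length features of a pooled run matrix."""
    counts = matrix.counts.astype(float)
    n_runs = counts.sum()
    if n_runs == 0:
        raise ValueError("run-length matrix has no runs")
    nb, max_len = counts.shape
    i = np.arange(1, nb + 1)[:, None].astype(float)
    r = np.arange(1, max_len + 1)[None, :].astype(float)

    def s(weight: np.ndarray) -> float:
        return float(np.sum(counts * weight) / n_runs)

    gln = float(np.sum(counts.sum(axis=1) ** 2) / n_runs)
    rln = float(np.sum(counts.sum(axis=0) ** 2) / n_runs)
    return {
        "ShortRunEmphasis": s(1.0 / r**2),
        "LongRunEmphasis": s(r**2),
        "GreyLevelNonUniformity": gln,
        "RunLengthNonUniformity": rln,
        "LowGreyLevelRunEmphasis": s(1.0 / i**2),
        "HighGreyLevelRunEmphasis": s(i**2),
        "ShortRunLowGreyLevelRunEmphasis": s(1.0 / (i**2 * r**2)),
        "ShortRunHighGreyLevelRunEmphasis": s(i**2 / r**2),
        "LongRunLowGreyLevelRunEmphasis": s(r**2 / i**2),
        "LongRunHighGreyLevelRunEmphasis": s(i**2 * r**2),
    }


def texture_vector(
    block: np.ndarray, params: TextureParams = TextureParams()
) -> dict[str, float]:
    """All 18 texture features of an intensity block, in canonical order."""
    binned = quantize(block, params)
    glcm = glcm_features(build_glcm(binned, params))
    glcm.pop("degenerate")
    glrlm = glrlm_features(build_glrlm(binned, params))
    out = {name: glcm[name] for name in GLCM_FEATURES}
    out.update({name: glrlm[name] for name in GLRLM_FEATURES})
    return out
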