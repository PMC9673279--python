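"""Trabecular bone morphometry: BV/TV, Tb.Th, Tb.Sp, Tb.N, BS/BV.

The estimators follow the parallel-plate mean-intercept-length model of
classical histomorphometry.  A test line laid across the block crosses a
sequence of bone and marrow intercepts; the trabecular number Tb.N is the
number of bone intercepts per unit line length, and the plate model then
gives

    Tb.Th = (BV/TV) / Tb.N       Tb.Sp = (1 - BV/TV) / Tb.N
    BS/BV = 2 * Tb.N / (BV/TV) = 2 / Tb.Th

so the plate identities Tb.Th * Tb.N = BV/TV and BS/BV * Tb.Th = 2 hold by
construction.  Intercepts are counted as maximal bone runs along lattice
lines; a bone run touching the block boundary still counts as one
intercept (equivalently, the missing bone-marrow transition at the edge is
booked as half a transition pair), which makes period-complete plate
phantoms exact.

The ``neighborhood_radius`` parameter is accepted for provenance parity
with the texture extractor but is not used by the plate-model estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np

from .texture import DIRECTIONS_13, _iter_lines, _run_length_encode

MORPHOMETRY_FEATURES = ("BVTV", "TbTh", "TbSp", "TbN", "BSBV")

AXES3 = ((1, 0, 0), (0, 1, 0), (0, 0, 1))

_DIRECTION_SETS = {"axes3": AXES3, "directions13": DIRECTIONS_13}


@dataclass(frozen=True)
class MorphometryParams:
    """Binarisation threshold and direction set for intercept counting.

    ``direction_set`` may be ``"axes3"`` (default), ``"directions13"``, or
    an explicit tuple of integer direction vectors — e.g. the plate normal
    for strongly oriented structures, where averaging over off-normal
    directions dilutes the intercept density.
    """

    threshold: float = 250.0
    neighborhood_radius: int = 4
    direction_set: str | tuple = "axes3"

    def directions(self) -> tuple[tuple[int, int, int], ...]:
        if isinstance(self.direction_set, str):
            try:
                return _DIRECTION_SETS[self.direction_set]
            except KeyError:
                raise ValueError(
                    f"unknown direction_set {self.direction_set!r}; expected "
                    "'axes3', 'directions13' or an explicit tuple of vectors"
                ) from None
        return tuple(tuple(int(c) for c in d) for d in self.direction_set)


def binarize(block: np.ndarray, params: MorphometryParams = MorphometryParams()) -> np.ndarray:
    """Bone mask of an intensity block: voxel is bone iff value >= threshold.

    The boundary is inclusive: a voxel exactly at the threshold is bone.
    """
    block = np.asarray(block)
    if block.size == 0:
        raise ValueError("empty block")
    return (block >= params.threshold).astype(np.uint8)


def _intercept_density(
    bone: np.ndarray, spacing: float, directions
) -> float:
    """Mean bone-intercept count per mm of test line, averaged over directions."""
    densities = []
    for d in directions:
        step_mm = spacing * sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
        intercepts = 0.0
        total_mm = 0.0
        for xs, ys, zs in _iter_lines(bone.shape, d):
            vals, _ = _run_length_encode(bone[xs, ys, zs])
            intercepts += np.count_nonzero(vals == 1)
            total_mm += xs.size * step_mm
        densities.append(intercepts / total_mm)
    return float(np.mean(densities))


def morphometry(
    bone: np.ndarray,
    spacing: float = 1.0,
    params: MorphometryParams = MorphometryParams(),
) -> dict[str, float]:
    """Plate-model morphometry of a binary bone block.

    Parameters
    ----------
    bone : ndarray of {0, 1}
        Binary block (1 = bone), e.g. from :func:`binarize`.
    spacing : float
        Isotropic voxel spacing in mm; Tb.Th/Tb.Sp scale linearly with it.

    Returns
    -------
    dict
        ``BVTV`` (proportion), ``TbTh``/``TbSp`` (mm), ``TbN``/``BSBV``
        (1/mm) and a ``tb_defined`` flag.  When the block is all bone or
        all marrow the intercept density is degenerate, so the Tb metrics
        are returned as NaN with ``tb_defined`` False while BV/TV is still
        reported.
    """
    bone = np.asarray(bone)
    if bone.ndim != 3 or bone.size == 0:
        raise ValueError("expected a non-empty 3D binary block")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    bvtv = float(bone.mean())
    if bvtv == 0.0 or bvtv == 1.0:
        return {
            "BVTV": bvtv,
            "TbTh": float("nan"),
            "TbSp": float("nan"),
            "TbN": float("nan"),
            "BSBV": float("nan"),
            "tb_defined": False,
        }
    tbn = _intercept_density(bone, spacing, params.directions())
    tbth = bvtv / tbn
    tbsp = (1.0 - bvtv) / tbn
    bsbv = 2.0 * tbn / bvtv
    return {
        "BVTV": bvtv,
        "TbTh": tbth,
        "TbSp": tbsp,
        "TbN": tbn,
        "BSBV": bsbv,
        "tb_defined": True,
    }


def morphometry_vector(
    block: np.ndarray,
    spacing: float = 1.0,
    params: MorphometryParams = MorphometryParams(),
) -> dict[str, float]:
    """Binarise an intensity block and compute the 5 morphometry features."""
    out = morphometry(binarize(block, params), spacing, params)
    return {name: out[name] for name in MORPHOMETRY_FEATURES}
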