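"""Condyle-to-fossa joint-space distances in five anatomical directions.

Masks are assumed already oriented in a standardized anatomical frame:
+x points medially (toward the midline), +y anteriorly and +z superiorly.
For each named direction the measurement is operationalised as a ray cast:
the condylar voxel most extreme along the direction is the surface start
point, a ray is cast along the direction, and the distance to the first
crossing of the fossa surface (trilinear 0.5 level of the mask) is the
joint-space width in mm.  Sub-voxel precision comes from linear
interpolation between the ray samples bracketing the crossing.

The anterolateral direction is the normalized (+y, -x) blend by default,
reflecting a 45-degree combination of anterior and lateral; it is
configurable because its exact anatomical definition varies.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from .volumes import MaskVolume

JOINT_SPACE_DIRECTIONS = ("anterior", "anterolateral", "medial", "superior", "posterior")


def _default_direction_vectors() -> dict[str, np.ndarray]:
    al = np.array([-1.0, 1.0, 0.0])
    return {
        "anterior": np.array([0.0, 1.0, 0.0]),
        "anterolateral": al / np.linalg.norm(al),
        "medial": np.array([1.0, 0.0, 0.0]),
        "superior": np.array([0.0, 0.0, 1.0]),
        "posterior": np.array([0.0, -1.0, 0.0]),
    }


class OverlappingMasksError(ValueError):
    """Raised when condyle and fossa segmentations share voxels."""


def _extreme_surface_point(mask: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Voxel index (float) of the mask voxel most extreme along a direction.

    Ties are broken lexicographically on the index triple, so repeated
    calls are deterministic.
    """
    idx = np.argwhere(mask > 0)
    proj = idx @ direction
    best = proj.max()
    candidates = idx[np.isclose(proj, best)]
    order = np.lexsort((candidates[:, 2], candidates[:, 1], candidates[:, 0]))
    return candidates[order[0]].astype(float)


def _first_crossing(
    fossa: np.ndarray,
    start: np.ndarray,
    direction: np.ndarray,
    spacing: float,
    step_voxels: float = 0.25,
) -> float:
    """Distance (mm) from start to the first 0.5-crossing of the fossa mask.

    Returns NaN when the ray leaves the volume without entering the fossa.
    """
    shape = np.array(fossa.shape, dtype=float)
    fossa_f = fossa.astype(float)
    # Upper bound on the ray length inside the volume, in voxel units.
    max_t = float(np.linalg.norm(shape))
    ts = np.arange(0.0, max_t, step_voxels)
    pts = start[None, :] + ts[:, None] * direction[None, :]
    inside = np.all((pts >= 0) & (pts <= shape - 1), axis=1)
    if not inside.any():
        return float("nan")
    ts = ts[inside]
    pts = pts[inside]
    vals = map_coordinates(fossa_f, pts.T, order=1, mode="constant", cval=0.0)
    above = vals >= 0.5
    if not above.any():
        return float("nan")
    k = int(np.argmax(above))
    if k == 0:
        t_cross = ts[0]
    else:
        v0, v1 = vals[k - 1], vals[k]
        frac = (0.5 - v0) / (v1 - v0) if v1 != v0 else 1.0
        t_cross = ts[k - 1] + frac * (ts[k] - ts[k - 1])
    return float(t_cross * spacing)


def joint_space_distances(
    condyle: MaskVolume,
    fossa: MaskVolume,
    direction_vectors: dict[str, np.ndarray] | None = None,
) -> dict[str, float]:
    """The five condyle-to-fossa distances (mm).

    Parameters
    ----------
    condyle, fossa : MaskVolume
        Disjoint binary segmentations on the same oriented grid.
    direction_vectors : dict, optional
        Override the standardized direction unit vectors (keys must cover
        :data:`JOINT_SPACE_DIRECTIONS`).

    Returns
    -------
    dict mapping direction name -> distance in mm; NaN marks a ray that
    exits the volume without intersecting the fossa.
    """
    if condyle.shape != fossa.shape:
        raise ValueError("condyle and fossa masks must share a grid")
    if condyle.spacing != fossa.spacing:
        raise ValueError("condyle and fossa masks must share voxel spacing")
    if np.any((condyle.voxels > 0) & (fossa.voxels > 0)):
        raise OverlappingMasksError("condyle and fossa segmentations overlap")
    if not condyle.voxels.any() or not fossa.voxels.any():
        raise ValueError("both masks must be non-empty")

    vectors = _default_direction_vectors()
    if direction_vectors:
        vectors.update({k: np.asarray(v, dtype=float) for k, v in direction_vectors.items()})

    out: dict[str, float] = {}
    for name in JOINT_SPACE_DIRECTIONS:
        d = vectors[name]
        d = d / np.linalg.norm(d)
        start = _extreme_surface_point(condyle.voxels, d)
        out[name] = _first_crossing(fossa.voxels, start, d, condyle.spacing)
    return out
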