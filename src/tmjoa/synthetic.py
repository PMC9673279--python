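"""Synthetic phantoms and cohorts with known ground truth.

Every downstream stage of the pipeline is exercised on data produced
here, so the generators are first-class, tested code.

Volumes
-------
* :func:`make_plate_phantom` builds a periodic parallel-plate stack
  (bone plates of thickness ``t`` separated by marrow gaps of ``g``
  along the z axis) whose bone-volume fraction and intercept geometry
  are known analytically — the canonical test substrate for the
  morphometry estimators.
* :func:`make_random_field_volume` thresholds a smoothed Gaussian random
  field at a quantile, producing an isotropic trabecular-like texture
  with a controllable bone-volume fraction.

Cohorts
-------
:func:`make_cohort` emulates a case-control study table (default 92
subjects, 79 features across six categories) with planted main effects
(standardized mean shifts on the diseased class) and planted pairwise
interaction effects (products of two features entering the
label-generating logit).  A main effect of size delta on a unit-variance
feature yields an expected Mann-Whitney AUC of Phi(delta / sqrt(2));
a pure interaction leaves both parents' marginal AUC at 0.5 while the
product feature separates the classes — the regime the screening and
ensemble stages are designed to exploit.

Intensities are HU-like and clipped to the analysis range [-1000, 2500].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .volumes import GreyVolume, MaskVolume

INTENSITY_MIN = -1000.0
INTENSITY_MAX = 2500.0

#: Default per-category feature counts (sum 79). The six categories mirror a
#: multi-source TMJ OA study: clinical signs, serum and saliva protein
#: levels, condylar and fossa radiomics, and joint-space distances. The
#: split is an assumption and fully configurable.
DEFAULT_CATEGORY_COUNTS: dict[str, int] = {
    "clinical": 8,
    "serum": 13,
    "saliva": 12,
    "condylar_radiomics": 23,
    "fossa_radiomics": 18,
    "joint_space": 5,
}


@dataclass(frozen=True)
class PlatePhantomSpec:
    """Geometry of a periodic parallel-plate bone phantom (voxel units)."""

    plate_thickness: int = 2
    gap: int = 3
    bone_intensity: float = 1200.0
    marrow_intensity: float = -800.0
    noise_sd: float = 0.0
    shape: tuple[int, int, int] = (30, 30, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plate_thickness < 1 or self.gap < 1:
            raise ValueError("plate_thickness and gap must be >= 1 voxel")
        period = self.plate_thickness + self.gap
        if any(s < period for s in self.shape):
            raise ValueError(
                f"every shape component must cover one period ({period} voxels)"
            )
        if not (self.bone_intensity > 250.0 > self.marrow_intensity):
            raise ValueError(
                "bone_intensity must exceed the morphometry threshold (250) "
                "and marrow_intensity must fall below it"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def make_plate_phantom(spec: PlatePhantomSpec) -> tuple[GreyVolume, MaskVolume]:
    """Periodic plate stack along z with optional additive Gaussian noise.

    z-layers ``0..t-1`` of each period are bone, the following ``g`` are
    marrow; on a period-complete grid the bone fraction is exactly
    ``t / (t + g)``.  Intensities are clipped to [-1000, 2500].  The mask
    marks the whole block as analysis region.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    z = np.arange(nz)
    bone_layer = (z % (spec.plate_thickness + spec.gap)) < spec.plate_thickness
    vol = np.where(bone_layer[None, None, :], spec.bone_intensity, spec.marrow_intensity)
    vol = np.broadcast_to(vol, spec.shape).astype(float).copy()
    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, size=spec.shape)
    vol = np.clip(vol, INTENSITY_MIN, INTENSITY_MAX)
    grey = GreyVolume(voxels=vol, spacing=1.0, volume_id=f"plate_t{spec.plate_thickness}_g{spec.gap}")
    mask = MaskVolume(voxels=np.ones(spec.shape, dtype=np.uint8), spacing=1.0)
    return grey, mask


def make_random_field_volume(
    bvtv_target: float,
    correlation_length: float = 2.0,
    shape: tuple[int, int, int] = (30, 30, 30),
    seed: int = 0,
    bone_intensity: float = 1200.0,
    marrow_intensity: float = -800.0,
) -> GreyVolume:
    """Trabecular-like volume from a thresholded smoothed Gaussian field.

    White noise is smoothed with a Gaussian kernel of scale
    ``correlation_length`` (voxels) and thresholded at the empirical
    ``1 - bvtv_target`` quantile, so the fraction of voxels mapped above
    the morphometry threshold (250) equals ``bvtv_target`` up to
    one-voxel quantile rounding.  Deterministic under ``seed``.
    """
    if not 0.0 < bvtv_target < 1.0:
        raise ValueError("bvtv_target must lie strictly between 0 and 1")
    if any(s < 2 for s in shape):
        raise ValueError(f"degenerate shape {shape}")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=correlation_length)
    cut = np.quantile(smooth, 1.0 - bvtv_target)
    vol = np.where(smooth > cut, bone_intensity, marrow_intensity)
    vol = np.clip(vol, INTENSITY_MIN, INTENSITY_MAX)
    return GreyVolume(voxels=vol, spacing=1.0, volume_id=f"field_bvtv{bvtv_target:g}")


@dataclass
class CohortSpec:
    """Design of a synthetic case-control cohort.

    ``main_effects`` are (feature_name, delta) pairs: the diseased-class
    mean of that feature is shifted by delta standard deviations.
    ``interaction_effects`` are (feature_i, feature_j, coefficient)
    triples: the product of the two (standard-normal) features enters the
    label-generating logit with that coefficient.
    """

    n_subjects: int = 92
    n_features_by_category: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_COUNTS)
    )
    main_effects: list[tuple[str, float]] = field(default_factory=list)
    interaction_effects: list[tuple[str, str, float]] = field(default_factory=list)
    label_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be >= 10")
        if not 0.0 < self.label_balance < 1.0:
            raise ValueError("label_balance must lie in (0, 1)")
        names = set(self.feature_names())
        for f, _ in self.main_effects:
            if f not in names:
                raise KeyError(f"main effect names unknown feature {f!r}")
        for fi, fj, _ in self.interaction_effects:
            for f in (fi, fj):
                if f not in names:
                    raise KeyError(f"interaction effect names unknown feature {f!r}")

    def feature_names(self) -> list[str]:
        return [
            f"{cat}_{k:02d}"
            for cat, count in self.n_features_by_category.items()
            for k in range(1, count + 1)
        ]

    def categories(self) -> dict[str, str]:
        return {
            f"{cat}_{k:02d}": cat
            for cat, count in self.n_features_by_category.items()
            for k in range(1, count + 1)
        }


@dataclass
class CohortTable:
    """Subjects x features with a binary disease status and category tags."""

    features: pd.DataFrame  # index: subject_id, columns: feature names
    labels: pd.Series  # 1 = diseased, 0 = control
    categories: dict[str, str]

    @property
    def n_subjects(self) -> int:
        return len(self.features)

    def to_csv(self, path, categories_path=None) -> None:
        """Write ``subject_id,status,<features...>`` plus a category sidecar."""
        out = self.features.copy()
        out.insert(0, "status", self.labels)
        out.to_csv(path, index_label="subject_id")
        if categories_path is not None:
            with open(categories_path, "w") as fh:
                yaml.safe_dump(self.categories, fh, sort_keys=True)

    @classmethod
    def from_csv(cls, path, categories_path=None) -> "CohortTable":
        df = pd.read_csv(path, index_col="subject_id")
        labels = df.pop("status").astype(int)
        cats: dict[str, str] = {}
        if categories_path is not None:
            with open(categories_path) as fh:
                cats = yaml.safe_load(fh) or {}
        return cls(features=df, labels=labels, categories=cats)


def make_cohort(spec: CohortSpec) -> CohortTable:
    """Generate a cohort with planted main and interaction effects.

    Features are standard normal within class.  Labels are drawn by a
    Bernoulli on the logistic of the interaction predictor, then resampled
    to the exact target balance by flipping the assignments with the
    smallest probability margin; main-effect features subsequently have
    their diseased-class mean shifted by delta, so the marginal effect
    size is exact by construction.  Bitwise reproducible under ``seed``.
    """
    rng = np.random.default_rng(spec.seed)
    names = spec.feature_names()
    n, f = spec.n_subjects, len(names)
    X = rng.standard_normal((n, f))
    cols = {name: k for k, name in enumerate(names)}

    logit = np.zeros(n)
    for fi, fj, coef in spec.interaction_effects:
        logit += coef * X[:, cols[fi]] * X[:, cols[fj]]
    base = np.log(spec.label_balance / (1.0 - spec.label_balance))
    p = 1.0 / (1.0 + np.exp(-(base + logit)))
    u = rng.uniform(size=n)
    # Exact balance: diseased = the n1 subjects with the largest margin p - u.
    n1 = int(round(n * spec.label_balance))
    n1 = min(max(n1, 1), n - 1)
    order = np.argsort(-(p - u), kind="stable")
    labels = np.zeros(n, dtype=int)
    labels[order[:n1]] = 1

    for fname, delta in spec.main_effects:
        X[labels == 1, cols[fname]] += delta

    ids = [f"S{k:03d}" for k in range(1, n + 1)]
    features = pd.DataFrame(X, index=pd.Index(ids, name="subject_id"), columns=names)
    return CohortTable(
        features=features,
        labels=pd.Series(labels, index=features.index, name="status"),
        categories=spec.categories(),
    )
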