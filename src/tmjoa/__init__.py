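"""tmjoa: quantitative bone-imaging biomarkers and interaction-aware
classification of temporomandibular joint osteoarthritis status.

The package covers the full analysis path: synthetic phantoms and
cohorts, volume I/O and VOI cropping, GLCM/GLRLM texture features,
trabecular morphometry, joint-space distances, univariate screening
statistics, interaction construction with AUC-gated selection, and a
repeated-CV boosted-stump ensemble with gain-based contribution ranking.
"""

from .volumes import (
    GreyVolume,
    MaskVolume,
    VOIBlock,
    AnisotropicSpacingError,
    read_volume,
    read_mask,
    write_volume,
    crop_voi,
)
from .synthetic import (
    PlatePhantomSpec,
    CohortSpec,
    CohortTable,
    make_plate_phantom,
    make_random_field_volume,
    make_cohort,
)
from .texture import (
    TextureParams,
    CooccurrenceMatrix,
    RunLengthMatrix,
    GLCM_FEATURES,
    GLRLM_FEATURES,
    TEXTURE_FEATURES,
    quantize,
    build_glcm,
    glcm_features,
    build_glrlm,
    glrlm_features,
    texture_vector,
)
from .morphometry import (
    MorphometryParams,
    MORPHOMETRY_FEATURES,
    binarize,
    morphometry,
    morphometry_vector,
)
from .jointspace import (
    JOINT_SPACE_DIRECTIONS,
    OverlappingMasksError,
    joint_space_distances,
)
from .stats import (
    mann_whitney_auc,
    mann_whitney_auc_matrix,
    q_values,
    group_t_test,
    icc,
    icc_gate,
    screen_features,
    ICCResult,
)
from .screening import (
    NormalizationState,
    SelectionRule,
    SelectionResult,
    fit_apply_normalization,
    interaction_pairs,
    build_interactions,
    select_features,
)
from .boosting import (
    Stump,
    BoostedModel,
    CVEnsembleResult,
    fit_boosted_stumps,
    run_repeated_cv,
    rank_contributions,
)
from .metrics import compute_metrics, interpret_auc, METRIC_NAMES

__version__ = "0.1.0"

RADIOMIC_FEATURES = TEXTURE_FEATURES + MORPHOMETRY_FEATURES


def radiomic_vector(block, texture_params=None, morphometry_params=None, spacing=1.0):
    """The full 23-feature radiomic vector of a VOI block.

    18 texture features (8 GLCM + 10 GLRLM) followed by the 5 bone
    morphometry features, in :data:`RADIOMIC_FEATURES` order.
    """
    import numpy as np

    from .morphometry import MorphometryParams
    from .texture import TextureParams
    from .volumes import VOIBlock

    if isinstance(block, VOIBlock):
        spacing = block.spacing
        block = block.voxels
    block = np.asarray(block)
    out = texture_vector(block, texture_params or TextureParams())
    out.update(
        morphometry_vector(block, spacing, morphometry_params or MorphometryParams())
    )
    return out
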