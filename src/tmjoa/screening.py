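"""Normalization, pairwise-interaction construction and AUC-gated selection.

This is the feature path feeding the classifier: z-score normalization
learned on training subjects only, interaction columns as elementwise
products of the two z-scored parents (for F base features there are
F(F-1)/2 of them — 3081 for F = 79), and two-sided AUC thresholds
(defaults: mains > 0.7, interactions > 0.65, on max(auc, 1 - auc)
computed from training subjects only, so held-out folds never leak into
selection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import mann_whitney_auc_matrix

logger = logging.getLogger(__name__)


@dataclass
class NormalizationState:
    """Per-feature mean/sd learned on training subjects only."""

    mean: pd.Series
    sd: pd.Series
    dropped: list[str]

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        kept = self.mean.index
        return (table[kept] - self.mean) / self.sd


def fit_apply_normalization(
    train: pd.DataFrame, apply: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None, NormalizationState]:
    """Learn z-scoring on the training table and apply it to both tables.

    Zero-variance features carry no ranking information and would divide
    by zero, so they are dropped with a logged warning.
    """
    if train.empty:
        raise ValueError("training table is empty")
    mean = train.mean()
    sd = train.std(ddof=0)
    dropped = sd.index[sd == 0].tolist()
    if len(dropped) == len(sd):
        raise ValueError("all features have zero variance on the training set")
    if dropped:
        logger.warning("dropping %d zero-variance feature(s): %s", len(dropped), dropped)
        mean = mean.drop(dropped)
        sd = sd.drop(dropped)
    state = NormalizationState(mean=mean, sd=sd, dropped=dropped)
    return state.apply(train), (state.apply(apply) if apply is not None else None), state


def interaction_pairs(feature_names: list[str]) -> list[tuple[int, int]]:
    """All unordered index pairs (i < j): F(F-1)/2 of them."""
    f = len(feature_names)
    return [(i, j) for i in range(f) for j in range(i + 1, f)]


def build_interactions(
    normalized: pd.DataFrame, pairs: list[tuple[int, int]] | None = None
) -> pd.DataFrame:
    """Interaction columns named ``A*B`` as products of z-scored parents."""
    names = list(normalized.columns)
    if pairs is None:
        pairs = interaction_pairs(names)
    f = len(names)
    for i, j in pairs:
        if not (0 <= i < f and 0 <= j < f):
            raise IndexError(f"interaction pair ({i}, {j}) out of range for {f} features")
    X = normalized.to_numpy()
    ii = np.array([i for i, _ in pairs], dtype=int)
    jj = np.array([j for _, j in pairs], dtype=int)
    prod = X[:, ii] * X[:, jj]
    cols = [f"{names[i]}*{names[j]}" for i, j in pairs]
    return pd.DataFrame(prod, index=normalized.index, columns=cols)


@dataclass(frozen=True)
class SelectionRule:
    """Two-sided AUC thresholds for mains and interactions."""

    main_auc_threshold: float = 0.7
    interaction_auc_threshold: float = 0.65
    fallback_top_k: int = 5

    def __post_init__(self) -> None:
        for thr in (self.main_auc_threshold, self.interaction_auc_threshold):
            if not 0.5 < thr <= 1.0:
                raise ValueError(f"AUC threshold must lie in (0.5, 1], got {thr}")


@dataclass
class SelectionResult:
    """Per-fold record of what was screened and what survived."""

    main_features: list[str]
    interaction_features: list[str]
    main_auc: pd.Series
    interaction_auc: pd.Series
    fallback_used: bool

    @property
    def selected(self) -> list[str]:
        return self.main_features + self.interaction_features


def select_features(
    mains: pd.DataFrame,
    interactions: pd.DataFrame,
    labels,
    rule: SelectionRule = SelectionRule(),
) -> SelectionResult:
    """Retain mains and interactions whose two-sided training AUC clears
    its threshold.

    Screening uses max(auc, 1 - auc) because an informative feature may
    point either way.  If nothing survives, the top-k mains by two-sided
    AUC are retained as a logged fallback so the classifier always has
    input.
    """
    labels = np.asarray(labels).astype(int)
    main_auc = pd.Series(
        mann_whitney_auc_matrix(mains.to_numpy(), labels), index=mains.columns
    )
    inter_auc = pd.Series(
        mann_whitney_auc_matrix(interactions.to_numpy(), labels),
        index=interactions.columns,
    )
    two_sided_main = np.maximum(main_auc, 1.0 - main_auc)
    two_sided_inter = np.maximum(inter_auc, 1.0 - inter_auc)
    kept_main = main_auc.index[two_sided_main > rule.main_auc_threshold].tolist()
    kept_inter = inter_auc.index[
        two_sided_inter > rule.interaction_auc_threshold
    ].tolist()
    fallback = False
    if not kept_main and not kept_inter:
        fallback = True
        k = min(rule.fallback_top_k, len(main_auc))
        kept_main = two_sided_main.sort_values(ascending=False).index[:k].tolist()
        logger.info("empty selection; falling back to top-%d mains", k)
    return SelectionResult(
        main_features=kept_main,
        interaction_features=kept_inter,
        main_auc=main_auc,
        interaction_auc=inter_auc,
        fallback_used=fallback,
    )
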