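"""Depth-1 gradient-boosted stumps under repeated stratified k-fold CV.

The classifier is a from-scratch gradient-boosting machine restricted to
depth-1 trees (decision stumps), trained on the logistic loss with
second-order (gradient/hessian) split gain as in standard boosted-tree
engines:

    gain = 1/2 [ G_L^2/(H_L+lambda) + G_R^2/(H_R+lambda)
                 - (G_L+G_R)^2/(H_L+H_R+lambda) ]

with leaf values -G/(H+lambda), shrunk by the learning rate.  The best
split per iteration is found by exhaustive scan over the midpoints of
sorted unique feature values; ties break toward the lower threshold and
lower feature index, so fits are deterministic given the seed.

``run_repeated_cv`` implements the evaluation protocol around it:
``repeats`` independent stratified ``folds``-fold partitions (100 x 5 at
study settings, 500 models in total), with normalization, interaction
construction and AUC-gated selection refit inside every training fold so
that no held-out subject ever influences them.  Each subject's final
probability is the average of the ``repeats`` models whose training set
excluded that subject.

The number of boosting iterations is tuned per model on an internal
stratified 80/20 split of the training fold with early stopping
(patience 20, max 500 rounds, learning rate 0.1 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .screening import (
    SelectionResult,
    SelectionRule,
    build_interactions,
    fit_apply_normalization,
    select_features,
)
from .stats import mann_whitney_auc_matrix
from .synthetic import CohortTable


@dataclass
class Stump:
    """A single depth-1 split: x < threshold goes left."""

    feature: int
    threshold: float
    left_value: float
    right_value: float
    gain: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        go_left = X[:, self.feature] < self.threshold
        return np.where(go_left, self.left_value, self.right_value)


@dataclass
class BoostedModel:
    """An additive log-odds model: sigmoid(base + lr * sum of stumps)."""

    stumps: list[Stump]
    learning_rate: float
    base_score: float
    feature_names: list[str]

    @property
    def n_iterations(self) -> int:
        return len(self.stumps)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        z = np.full(X.shape[0], self.base_score)
        for stump in self.stumps:
            z += self.learning_rate * stump.predict(X)
        return z

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))

    def gain_by_feature(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for stump in self.stumps:
            name = self.feature_names[stump.feature]
            out[name] = out.get(name, 0.0) + stump.gain
        return out


def _best_stump(
    X: np.ndarray,
    order: np.ndarray,
    g: np.ndarray,
    h: np.ndarray,
    reg_lambda: float,
    min_leaf: int = 1,
) -> Stump | None:
    """Exhaustive best-gain split over all features and midpoints.

    ``order`` is the precomputed (n, F) argsort of each column of X.
    Splits leaving fewer than ``min_leaf`` samples on either side are
    rejected.  Returns None when no valid split exists.
    """
    n, f = X.shape
    Xs = np.take_along_axis(X, order, axis=0)
    gs = g[order]
    hs = h[order]
    GL = np.cumsum(gs, axis=0)[:-1]  # left sums for splits after row k
    HL = np.cumsum(hs, axis=0)[:-1]
    G, H = g.sum(), h.sum()
    GR = G - GL
    HR = H - HL
    parent = G * G / (H + reg_lambda)
    gains = 0.5 * (GL**2 / (HL + reg_lambda) + GR**2 / (HR + reg_lambda) - parent)
    valid = Xs[:-1] < Xs[1:]  # no split between tied values
    if min_leaf > 1:
        k = np.arange(1, n)  # left-leaf size at each split position
        size_ok = (k >= min_leaf) & (n - k >= min_leaf)
        valid = valid & size_ok[:, None]
    gains = np.where(valid, gains, -np.inf)
    if not np.isfinite(gains).any():
        return None
    k, j = np.unravel_index(np.argmax(gains), gains.shape)
    threshold = 0.5 * (Xs[k, j] + Xs[k + 1, j])
    lam = reg_lambda
    left = -GL[k, j] / (HL[k, j] + lam)
    right = -GR[k, j] / (HR[k, j] + lam)
    return Stump(
        feature=int(j),
        threshold=float(threshold),
        left_value=float(left),
        right_value=float(right),
        gain=float(gains[k, j]),
    )


def _auc(scores: np.ndarray, y: np.ndarray) -> float:
    return float(mann_whitney_auc_matrix(scores[:, None], y)[0])


def fit_boosted_stumps(
    X,
    y,
    learning_rate: float = 0.1,
    max_iter: int = 500,
    validation_fraction: float = 0.2,
    patience: int = 20,
    reg_lambda: float = 1.0,
    min_leaf: int = 10,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> BoostedModel:
    """Fit a logistic-loss boosted-stump model with early stopping.

    An internal stratified ``validation_fraction`` split of the training
    data monitors validation log-loss; boosting stops after ``patience``
    rounds without improvement and the model is truncated to the best
    round.  Set ``validation_fraction=0`` to disable tuning and run
    ``max_iter`` rounds.  ``min_leaf`` rejects splits that isolate fewer
    samples than that on either side — the standard small-cohort guard of
    boosted-tree engines against memorising single subjects; it is capped
    at a quarter of the training size so tiny folds remain splittable.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        feature_names = feature_names or [f"f{k}" for k in range(X.shape[1])]
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")

    use_val = validation_fraction > 0 and counts.min() >= 2
    if use_val:
        idx_tr, idx_val = train_test_split(
            np.arange(len(y)),
            test_size=validation_fraction,
            stratify=y,
            random_state=seed % (2**32),
        )
    else:
        idx_tr = np.arange(len(y))
        idx_val = np.empty(0, dtype=int)
    Xt, yt = X[idx_tr], y[idx_tr]
    Xv, yv = X[idx_val], y[idx_val]
    if use_val and len(np.unique(yv)) < 2:
        use_val = False

    prev = yt.mean()
    base = float(np.log(prev / (1.0 - prev)))
    order = np.argsort(Xt, axis=0, kind="stable")

    eff_min_leaf = min(min_leaf, max(1, len(yt) // 4))
    stumps: list[Stump] = []
    z_tr = np.full(len(yt), base)
    z_val = np.full(len(yv), base)
    best_loss = np.inf
    best_iter = 0
    stall = 0
    for it in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-z_tr))
        g = p - yt
        h = p * (1.0 - p)
        stump = _best_stump(Xt, order, g, h, reg_lambda, eff_min_leaf)
        if stump is None:
            break
        stumps.append(stump)
        z_tr += learning_rate * stump.predict(Xt)
        if use_val:
            z_val += learning_rate * stump.predict(Xv)
            pv = 1.0 / (1.0 + np.exp(-z_val))
            val_loss = -float(
                np.mean(yv * np.log(pv + 1e-12) + (1 - yv) * np.log(1 - pv + 1e-12))
            )
            if val_loss < best_loss - 1e-12:
                best_loss = val_loss
                best_iter = it + 1
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    break
    if use_val:
        stumps = stumps[:best_iter] if best_iter > 0 else stumps[:1]
    return BoostedModel(
        stumps=stumps,
        learning_rate=learning_rate,
        base_score=base,
        feature_names=feature_names,
    )


@dataclass
class FoldRecord:
    """Bookkeeping for one fitted fold model (leakage-audit friendly)."""

    repeat: int
    fold: int
    train_ids: list
    test_ids: list
    model: BoostedModel
    selection: SelectionResult


@dataclass
class CVEnsembleResult:
    """Everything produced by a repeated-CV run."""

    repeats: int
    folds: int
    records: list[FoldRecord]
    oof_probability: pd.Series  # mean held-out probability per subject
    labels: pd.Series

    @property
    def n_models(self) -> int:
        return len(self.records)

    def models_excluding(self, subject_id) -> list[FoldRecord]:
        return [r for r in self.records if subject_id in r.test_ids]

    def total_gain(self) -> pd.Series:
        total: dict[str, float] = {}
        for rec in self.records:
            for name, gain in rec.model.gain_by_feature().items():
                total[name] = total.get(name, 0.0) + gain
        return pd.Series(total).sort_values(ascending=False)


def run_repeated_cv(
    cohort: CohortTable,
    rule: SelectionRule = SelectionRule(),
    repeats: int = 100,
    folds: int = 5,
    seed: int = 0,
    use_interactions: bool = True,
    **boost_kwargs,
) -> CVEnsembleResult:
    """Repeated stratified k-fold CV with per-fold screening and fitting.

    Per repeat a fresh stratified partition is drawn; per fold the
    pipeline is normalization -> interaction construction -> AUC-gated
    selection -> boosted-stump fit, everything learned from the training
    subjects of that fold only, then applied to the held-out subjects.
    """
    y = cohort.labels
    features = cohort.features
    class_min = int(y.value_counts().min())
    if folds > class_min:
        raise ValueError(
            f"cannot stratify {folds} folds with only {class_min} subjects "
            "in the smaller class"
        )
    rng = np.random.default_rng(seed)
    records: list[FoldRecord] = []
    prob_sum = pd.Series(0.0, index=features.index)
    prob_count = pd.Series(0, index=features.index)

    for rep in range(repeats):
        splitter = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        for fold, (tr, te) in enumerate(splitter.split(features, y)):
            train_x = features.iloc[tr]
            test_x = features.iloc[te]
            norm_train, norm_test, _ = fit_apply_normalization(train_x, test_x)
            if use_interactions:
                inter_train = build_interactions(norm_train)
                inter_test = build_interactions(norm_test)
            else:
                inter_train = norm_train.iloc[:, :0]
                inter_test = norm_test.iloc[:, :0]
            sel = select_features(norm_train, inter_train, y.iloc[tr], rule)
            design_train = pd.concat(
                [norm_train[sel.main_features], inter_train[sel.interaction_features]],
                axis=1,
            )
            design_test = pd.concat(
                [norm_test[sel.main_features], inter_test[sel.interaction_features]],
                axis=1,
            )
            model = fit_boosted_stumps(
                design_train,
                y.iloc[tr].to_numpy(),
                seed=int(rng.integers(2**31)),
                **boost_kwargs,
            )
            proba = model.predict_proba(design_test.to_numpy())
            prob_sum.iloc[te] += proba
            prob_count.iloc[te] += 1
            records.append(
                FoldRecord(
                    repeat=rep,
                    fold=fold,
                    train_ids=features.index[tr].tolist(),
                    test_ids=features.index[te].tolist(),
                    model=model,
                    selection=sel,
                )
            )
    oof = prob_sum / prob_count
    return CVEnsembleResult(
        repeats=repeats,
        folds=folds,
        records=records,
        oof_probability=oof.rename("oof_probability"),
        labels=y,
    )


def rank_contributions(result: CVEnsembleResult, top_share: float = 0.9) -> pd.DataFrame:
    """Gain-based contribution ledger over all fitted models.

    Per-feature gains are summed over every model, normalized to 1 and
    sorted descending; the minimal prefix whose cumulative share exceeds
    ``top_share`` is flagged as the top contributors.  Identical duplicate
    columns split their shared gain between them according to the stumps'
    deterministic lower-index tie-break.
    """
    gain = result.total_gain()
    total = gain.sum()
    if total <= 0:
        raise ValueError("no split gain accumulated; cannot rank contributions")
    share = gain / total
    cumulative = share.cumsum()
    # Minimal prefix strictly exceeding the share target.
    n_top = int(np.searchsorted(cumulative.to_numpy(), top_share) + 1)
    out = pd.DataFrame(
        {
            "feature": share.index,
            "share": share.to_numpy(),
            "cumulative_share": cumulative.to_numpy(),
        }
    )
    out["top_contributor"] = np.arange(len(out)) < n_top
    return out
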