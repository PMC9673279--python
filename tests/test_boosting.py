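"""Boosted stumps and the repeated-CV ensemble protocol."""

import numpy as np
import pandas as pd
import pytest

from tmjoa.boosting import (
    _best_stump,
    fit_boosted_stumps,
    rank_contributions,
    run_repeated_cv,
)
from tmjoa.metrics import compute_metrics
from tmjoa.stats import mann_whitney_auc
from tmjoa.synthetic import CohortSpec, make_cohort
from oracles import best_stump_oracle


class TestStumpFit:
    def test_perfectly_separable_1d(self):
        X = np.linspace(0, 1, 40).reshape(-1, 1)
        y = (X[:, 0] > 0.5).astype(int)
        model = fit_boosted_stumps(X, y, validation_fraction=0.0, max_iter=5, min_leaf=1)
        auc = mann_whitney_auc(model.predict_proba(X), y)[0]
        assert auc == 1.0
        assert model.n_iterations <= 5

    def test_single_stump_matches_exhaustive_search(self, rng):
        # one boosting iteration from the prior: gradients are known in
        # closed form, so the chosen split must equal the brute-force best
        for trial in range(20):
            n = int(rng.integers(10, 50))
            X = rng.normal(size=(n, 3))
            y = (rng.uniform(size=n) < 0.5).astype(int)
            if y.sum() in (0, n):
                continue
            model = fit_boosted_stumps(
                X, y, validation_fraction=0.0, max_iter=1, min_leaf=1
            )
            stump = model.stumps[0]
            p0 = y.mean()
            g = np.full(n, p0) - y
            h = np.full(n, p0 * (1 - p0))
            best = max(
                (best_stump_oracle(X[:, j], g, h, lam=1.0) for j in range(3)),
                key=lambda b: b[1] if b else -np.inf,
            )
            assert stump.gain == pytest.approx(best[1], rel=1e-9)

    def test_min_leaf_respected(self, rng):
        X = rng.normal(size=(60, 2))
        y = (rng.uniform(size=60) < 0.5).astype(int)
        y[:2] = [0, 1]
        model = fit_boosted_stumps(X, y, validation_fraction=0.0, max_iter=20, min_leaf=10)
        for stump in model.stumps:
            left = (X[:, stump.feature] < stump.threshold).sum()
            assert 10 <= left <= 50

    def test_noise_labels_stop_early_and_do_not_separate(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 10))
        y = rng.integers(0, 2, size=80)
        model = fit_boosted_stumps(X, y, seed=0)
        assert model.n_iterations < 500  # early stopping engaged

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_boosted_stumps(rng.normal(size=(10, 2)), np.ones(10, dtype=int))

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(60, 5))
        y = (X[:, 0] + rng.normal(0, 1, 60) > 0).astype(int)
        m1 = fit_boosted_stumps(X, y, seed=7)
        m2 = fit_boosted_stumps(X, y, seed=7)
        assert [s.threshold for s in m1.stumps] == [s.threshold for s in m2.stumps]


@pytest.fixture(scope="module")
def signal_cv_result():
    cohort = make_cohort(
        CohortSpec(
            seed=1,
            main_effects=[("clinical_01", 2.0), ("serum_01", 2.0)],
            interaction_effects=[("fossa_radiomics_01", "condylar_radiomics_01", 2.0)],
        )
    )
    return cohort, run_repeated_cv(cohort, repeats=5, folds=5, seed=1)


class TestRepeatedCV:
    def test_model_count_law(self, signal_cv_result):
        _, result = signal_cv_result
        assert result.n_models == 5 * 5

    def test_every_subject_predicted_by_exactly_r_excluding_models(self, signal_cv_result):
        cohort, result = signal_cv_result
        for sid in cohort.features.index:
            excluding = result.models_excluding(sid)
            assert len(excluding) == 5
            for rec in excluding:
                assert sid not in rec.train_ids

    def test_train_test_partition_disjoint_and_complete(self, signal_cv_result):
        cohort, result = signal_cv_result
        all_ids = set(cohort.features.index)
        for rec in result.records:
            assert set(rec.train_ids) | set(rec.test_ids) == all_ids
            assert not set(rec.train_ids) & set(rec.test_ids)

    def test_planted_signal_gives_high_oof_auc(self, signal_cv_result):
        _, result = signal_cv_result
        m = compute_metrics(result.oof_probability, result.labels)
        assert m["auc"] > 0.8

    def test_too_many_folds_rejected(self):
        cohort = make_cohort(CohortSpec(seed=2, n_subjects=12))
        with pytest.raises(ValueError):
            run_repeated_cv(cohort, repeats=1, folds=10)


class TestContributions:
    def test_shares_normalized_and_sorted(self, signal_cv_result):
        _, result = signal_cv_result
        ranked = rank_contributions(result)
        assert ranked["share"].sum() == pytest.approx(1.0, abs=1e-9)
        assert ranked["share"].is_monotonic_decreasing
        assert ranked["top_contributor"].any()

    def test_planted_features_lead_the_ranking(self, signal_cv_result):
        _, result = signal_cv_result
        top = set(rank_contributions(result).head(3)["feature"])
        assert {"clinical_01", "serum_01"} <= top

    def test_top_set_is_minimal_prefix_over_90_percent(self, signal_cv_result):
        _, result = signal_cv_result
        ranked = rank_contributions(result)
        top = ranked[ranked["top_contributor"]]
        assert top["share"].sum() > 0.9
        assert top["share"].sum() - top["share"].iloc[-1] <= 0.9

    def test_duplicated_informative_column_splits_share(self):
        rng = np.random.default_rng(3)
        n = 80
        x = rng.normal(size=n)
        y = (x + rng.normal(0, 0.5, n) > 0).astype(int)
        X = pd.DataFrame({"dup1": x, "dup2": x.copy(), "noise": rng.normal(size=n)})
        model = fit_boosted_stumps(X, y, validation_fraction=0.0, max_iter=30, seed=0)
        gains = model.gain_by_feature()
        # deterministic lower-index tie-break: all shared gain lands on dup1
        assert gains.get("dup1", 0.0) > 0
        assert gains.get("dup2", 0.0) == 0.0


class TestCalibration:
    def test_label_permuted_cohorts_average_chance_auc(self):
        base = make_cohort(CohortSpec(seed=11))
        rng = np.random.default_rng(11)
        aucs = []
        for _ in range(6):
            permuted = base
            permuted.labels[:] = rng.permutation(base.labels.to_numpy())
            result = run_repeated_cv(permuted, repeats=2, folds=5, seed=int(rng.integers(2**31)))
            aucs.append(compute_metrics(result.oof_probability, result.labels)["auc"])
        assert 0.4 <= np.mean(aucs) <= 0.6
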