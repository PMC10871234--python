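"""Feature recipes, grouped splitting, tuning, stacking, attribution."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from frailspan.endpoints import label_assessments
from frailspan.ensemble import (
    CandidateModel,
    FeatureBuilder,
    assemble_rows,
    complete_rows,
    evaluate,
    explain_top_member,
    permutation_shapley,
    split_grouped,
    stack,
    train_ensemble,
    tune_candidates,
    upsample_events,
)
from frailspan.fgi import default_catalog
from frailspan.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="module")
def ml_rows(catalog):
    config = CohortConfig(n_mice_per_group=12, strains=("DO",), seed=17)
    mice, assessments, _ = generate_cohort(config)
    labels = label_assessments(assessments, mice)
    rows = assemble_rows(assessments, mice, labels, catalog)
    return mice, rows


class TestAssemble:
    def _toy(self, catalog, weights, days):
        n = len(weights)
        assessments = pd.DataFrame(
            {
                "mouse_id": "m1",
                "date": pd.to_datetime("2020-01-01") + pd.to_timedelta(days, unit="D"),
                "age_days": 900.0 + np.asarray(days),
                "weight_g": weights,
                "temp_C": 36.0,
            }
        )
        for name in catalog.names:
            assessments[name] = 0.0
        mice = pd.DataFrame(
            {"mouse_id": ["m1"], "strain": "DO", "sex": "F", "diet": "AL",
             "lifespan_days": [2000.0]}
        )
        labels = assessments[["mouse_id", "date"]].assign(is_95pll=False)
        return assessments, mice, labels

    def test_thirty_day_percent_change(self, catalog):
        assessments, mice, labels = self._toy(catalog, [30.0, 29.0, 27.0], [0, 15, 30])
        rows = assemble_rows(assessments, mice, labels, catalog)
        # at day 30 the earliest observation in [0, 30) is day 0: (27-30)/30
        assert rows.loc[2, "wt_pct30"] == pytest.approx(-10.0)
        # at day 15 the window holds day 0 only
        assert rows.loc[1, "wt_pct30"] == pytest.approx(100 * (29 - 30) / 30)
        assert np.isnan(rows.loc[0, "wt_pct30"])

    def test_short_followup_mice_excluded(self, catalog):
        assessments, mice, labels = self._toy(catalog, [30.0, 29.0], [0, 21])
        with pytest.raises(ValueError, match="30 days"):
            assemble_rows(assessments, mice, labels, catalog)

    def test_integer_rescaling(self, catalog):
        assessments, mice, labels = self._toy(catalog, [30.0, 29.0, 28.0], [0, 15, 30])
        three = next(n for n, lv in catalog.items if lv == 3)
        assessments[three] = [0.0, 0.5, 1.0]
        rows = assemble_rows(assessments, mice, labels, catalog)
        assert rows[f"{three}__int"].tolist() == [1.0, 2.0, 3.0]
        assert rows.loc[2, f"{three}__d30"] == 2.0  # 3 - 1 over the window


class TestFeatureBuilder:
    def test_zero_variance_items_filtered_and_pca_shapes(self, ml_rows, catalog):
        _, rows = ml_rows
        rows = complete_rows(rows, "M3", catalog)
        b = FeatureBuilder("M3", catalog).fit(rows)
        kept = b.pca_items_[1]
        assert "nasal_discharge__int" not in kept
        assert "vaginal_uterine_prolapse__int" not in kept
        assert sum(n.startswith("pc_item") for n in b.feature_names_) == 5
        assert sum(n.startswith("pc_delta") for n in b.feature_names_) == 5

    def test_training_columns_standardized_and_components_orthogonal(self, ml_rows, catalog):
        _, rows = ml_rows
        rows = complete_rows(rows, "M2", catalog)
        b = FeatureBuilder("M2", catalog).fit(rows)
        x = b.transform(rows)
        cont = [i for i, n in enumerate(b.feature_names_) if not n.startswith("ind_")]
        assert np.allclose(x[:, cont].mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(x[:, cont].std(axis=0), 1.0, atol=1e-9)
        pca, kept = b.pca_items_
        scores = pca.transform(rows[kept].to_numpy(float))
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()

    def test_recipe_nesting(self, ml_rows, catalog):
        _, rows = ml_rows
        rows = complete_rows(rows, "M3", catalog)
        names = {}
        for r in ("M0", "M1", "M2", "M3"):
            names[r] = set(FeatureBuilder(r, catalog).fit(rows).feature_names_)
        assert names["M0"] < names["M1"] < names["M2"] < names["M3"]

    def test_transform_uses_training_constants(self, ml_rows, catalog):
        _, rows = ml_rows
        rows = complete_rows(rows, "M1", catalog)
        half = len(rows) // 2
        b = FeatureBuilder("M1", catalog).fit(rows.iloc[:half])
        x_new = b.transform(rows.iloc[half:])
        # held-out rows are not exactly standardized under training constants
        assert not np.allclose(x_new.mean(axis=0), 0.0, atol=1e-3)


class TestSplit:
    def _mice(self, n, diets=("AL",)):
        return pd.DataFrame(
            {"mouse_id": [f"m{i}" for i in range(n)],
             "diet": np.tile(diets, n // len(diets))}
        )

    def test_exact_quarter_and_determinism(self):
        mice = self._mice(100)
        p1 = split_grouped(mice, seed=3)
        p2 = split_grouped(mice, seed=3)
        assert len(p1.test_mouse_ids) == 25
        assert p1.test_mouse_ids == p2.test_mouse_ids and p1.folds == p2.folds

    def test_stratified_allocation(self):
        mice = self._mice(40, diets=("AL", "CR40"))
        plan = split_grouped(mice, seed=1)
        test = mice[mice["mouse_id"].isin(plan.test_mouse_ids)]
        assert test["diet"].value_counts().tolist() == [5, 5]

    def test_test_and_folds_disjoint_partition(self):
        mice = self._mice(60, diets=("AL", "IF1", "CR40"))
        plan = split_grouped(mice, seed=9)
        assert not (plan.test_mouse_ids & set(plan.folds))
        assert set(plan.folds) | plan.test_mouse_ids == set(mice["mouse_id"])
        assert set(plan.folds.values()) == {1, 2, 3, 4, 5}

    def test_small_stratum_pooled_with_warning(self):
        mice = self._mice(33, diets=("AL",))
        mice.loc[:2, "diet"] = "RARE"
        with pytest.warns(UserWarning, match="pooled"):
            split_grouped(mice, seed=0)

    def test_too_few_mice_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            split_grouped(self._mice(4), seed=0)


class TestUpsample:
    def test_balances_to_majority(self):
        y = np.array([True] * 100 + [False] * 400)
        idx = upsample_events(y, np.random.default_rng(0))
        assert len(idx) == 800
        assert y[idx].sum() == 400

    def test_balanced_input_unchanged(self):
        y = np.array([True, False] * 10)
        assert len(upsample_events(y, np.random.default_rng(0))) == 20

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            upsample_events(np.ones(5, dtype=bool), np.random.default_rng(0))


def _train_setup(ml_rows, catalog, recipes=("M0",)):
    mice, rows = ml_rows
    rows = complete_rows(rows, max(recipes), catalog)
    used = mice[mice["mouse_id"].isin(rows["mouse_id"])]
    plan = split_grouped(used, seed=5)
    train = rows[~rows["mouse_id"].isin(plan.test_mouse_ids)].reset_index(drop=True)
    test = rows[rows["mouse_id"].isin(plan.test_mouse_ids)].reset_index(drop=True)
    return plan, train, test


class TestTuning:
    def test_single_config_full_oof_coverage(self, ml_rows, catalog):
        plan, train, _ = _train_setup(ml_rows, catalog)
        cands = tune_candidates(
            train, plan, learners=("RLR",), recipes=("M0",),
            grids={"RLR": [{"C": 1.0}]}, catalog=catalog, seed=2,
        )
        assert len(cands) == 1
        assert cands[0].params == {"C": 1.0}
        assert not np.isnan(cands[0].oof_pred).any()

    def test_noise_features_give_null_auc(self, catalog):
        rng = np.random.default_rng(8)
        n_mice, n_obs = 40, 12
        rows = pd.DataFrame(
            {
                "mouse_id": np.repeat([f"m{i}" for i in range(n_mice)], n_obs),
                "age_days": rng.normal(1000, 100, n_mice * n_obs),
                "diet": "AL", "sex": "F", "strain": "DO",
                "is_95pll": rng.random(n_mice * n_obs) < 0.3,
            }
        )
        mice = pd.DataFrame({"mouse_id": [f"m{i}" for i in range(n_mice)], "diet": "AL"})
        plan = split_grouped(mice, seed=0)
        train = rows[~rows["mouse_id"].isin(plan.test_mouse_ids)].reset_index(drop=True)
        cands = tune_candidates(
            train, plan, learners=("RLR",), recipes=("M0",),
            grids={"RLR": [{"C": 1.0}]}, catalog=catalog, seed=1,
        )
        assert 0.42 <= cands[0].cv_auc <= 0.58

    def test_planted_linear_signal_recovered(self, catalog):
        rng = np.random.default_rng(9)
        n_mice, n_obs = 40, 12
        age = rng.normal(1000, 100, n_mice * n_obs)
        rows = pd.DataFrame(
            {
                "mouse_id": np.repeat([f"m{i}" for i in range(n_mice)], n_obs),
                "age_days": age, "diet": "AL", "sex": "F", "strain": "DO",
                "is_95pll": rng.random(n_mice * n_obs)
                < 1 / (1 + np.exp(-(age - 1000) / 25.0)),
            }
        )
        mice = pd.DataFrame({"mouse_id": [f"m{i}" for i in range(n_mice)], "diet": "AL"})
        plan = split_grouped(mice, seed=0)
        train = rows[~rows["mouse_id"].isin(plan.test_mouse_ids)].reset_index(drop=True)
        cands = tune_candidates(
            train, plan, learners=("RLR",), recipes=("M0",),
            grids={"RLR": [{"C": 1.0}]}, catalog=catalog, seed=1,
        )
        assert cands[0].cv_auc > 0.9

    def test_max_grid_size_respected(self, ml_rows, catalog):
        plan, train, _ = _train_setup(ml_rows, catalog)
        big_grid = {"RLR": [{"C": c} for c in np.logspace(-3, 3, 60)]}
        cands = tune_candidates(
            train, plan, learners=("RLR",), recipes=("M0",),
            grids=big_grid, max_configs=25, catalog=catalog, seed=2,
        )
        assert cands[0].params in big_grid["RLR"]


class TestStack:
    def test_single_candidate_rank_preserved(self, ml_rows, catalog):
        plan, train, test = _train_setup(ml_rows, catalog)
        cands = tune_candidates(
            train, plan, learners=("RLR",), recipes=("M0",),
            grids={"RLR": [{"C": 1.0}]}, catalog=catalog, seed=2,
        )
        model = stack(cands, train, plan, catalog=catalog, seed=3)
        assert len(model.members) == 1 and model.members[0].weight > 0
        p_ens = model.predict_proba(test)
        member = model.members[0]
        p_single = member.model.predict_proba(member.builder.transform(test))[:, 1]
        rho, _ = stats.spearmanr(p_ens, p_single)
        assert rho == pytest.approx(1.0)

    def test_duplicate_candidates_do_not_change_auc(self, ml_rows, catalog):
        plan, train, test = _train_setup(ml_rows, catalog)
        cands = tune_candidates(
            train, plan, learners=("RLR",), recipes=("M0",),
            grids={"RLR": [{"C": 1.0}]}, catalog=catalog, seed=2,
        )
        twice = cands + [
            CandidateModel(**{**cands[0].__dict__})
        ]
        m1 = stack(cands, train, plan, catalog=catalog, seed=3)
        m2 = stack(twice, train, plan, catalog=catalog, seed=3)
        assert evaluate(m1, test)["auc_roc"] == pytest.approx(
            evaluate(m2, test)["auc_roc"], abs=1e-6
        )

    def test_huge_penalty_raises_all_zero_error(self, ml_rows, catalog):
        plan, train, _ = _train_setup(ml_rows, catalog)
        cands = tune_candidates(
            train, plan, learners=("RLR",), recipes=("M0",),
            grids={"RLR": [{"C": 1.0}]}, catalog=catalog, seed=2,
        )
        with pytest.raises(ValueError, match="penalty"):
            stack(cands, train, plan, lambdas=(1e6,), catalog=catalog, seed=3)


class TestEvaluate:
    def test_perfect_probabilities(self, ml_rows, catalog):
        plan, train, test = _train_setup(ml_rows, catalog)
        # check the metric arithmetic directly through a stub ensemble
        from frailspan.ensemble import EnsembleModel

        class StubMember:
            weight = 1.0

            class builder:
                @staticmethod
                def transform(rows):
                    return rows

            class model:
                @staticmethod
                def predict_proba(rows):
                    y = rows["is_95pll"].to_numpy(float)
                    return np.column_stack([1 - y, y])

        model = EnsembleModel(members=[StubMember()], intercept=-10.0,
                              meta_lambda=0.0, seed=0)
        model.members[0].weight = 40.0
        rep = evaluate(model, test)
        assert rep["thresholds"].iloc[0]["accuracy"] == 1.0
        assert rep["auc_roc"] == 1.0

    def test_one_class_test_rejected(self, ml_rows, catalog):
        plan, train, test = _train_setup(ml_rows, catalog)
        from frailspan.ensemble import EnsembleModel

        model = EnsembleModel(members=[], intercept=0.0, meta_lambda=0.0, seed=0)
        with pytest.raises(ValueError, match="single outcome class"):
            evaluate(model, test.assign(is_95pll=True))


class TestShapley:
    def test_additivity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        bg = rng.normal(size=(30, 5))
        predict = lambda z: 1 / (1 + np.exp(-(z[:, 0] + 0.5 * z[:, 1] * z[:, 2])))
        phi = permutation_shapley(predict, X, bg, n_permutations=8, rng=rng)
        expected = predict(X) - predict(bg).mean()
        assert np.allclose(phi.sum(axis=1), expected, atol=1e-10)

    def test_unused_feature_gets_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 4))
        bg = rng.normal(size=(20, 4))
        predict = lambda z: z[:, 0] * 2.0
        phi = permutation_shapley(predict, X, bg, n_permutations=5, rng=rng)
        assert np.allclose(phi[:, 1:], 0.0)

    def test_planted_signal_dominates_attribution(self, ml_rows, catalog):
        plan, train, test = _train_setup(ml_rows, catalog)
        cands = tune_candidates(
            train, plan, learners=("RLR",), recipes=("M0",),
            grids={"RLR": [{"C": 1.0}]}, catalog=catalog, seed=2,
        )
        model = stack(cands, train, plan, catalog=catalog, seed=3)
        attr = explain_top_member(model, test, n_permutations=5, max_rows=40, seed=0)
        # age dominates 95PLL risk in the M0 recipe (age + diet indicators)
        assert attr.iloc[0]["feature"] == "age_days"


def test_no_leakage_deleting_test_rows(ml_rows, catalog):
    """Fitted ensemble is identical with or without test-mouse rows on disk."""
    mice, rows = ml_rows
    m1, p1, tr1, te1 = train_ensemble(
        rows, mice, learners=("RLR",), recipes=("M0", "M2"),
        grids={"RLR": [{"C": 1.0}]}, seed=42,
    )
    rows_wo_test = rows[~rows["mouse_id"].isin(p1.test_mouse_ids)]
    m2, p2, tr2, _ = train_ensemble(
        rows_wo_test, mice, learners=("RLR",), recipes=("M0", "M2"),
        grids={"RLR": [{"C": 1.0}]}, seed=42, plan=p1,
    )
    assert p1.folds == p2.folds
    assert np.array_equal(m1.predict_proba(te1), m2.predict_proba(te1))
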