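"""Imputers: tie-breaks, donor logic, tuning, stacking, shared invariants."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from imputebench import (OUTCOME, TARGET, ImputerConfig, MissingScenario,
                         ampute, encode_features, generate_cohort, impute,
                         impute_classifier, impute_knn, impute_mice_pmm,
                         impute_mode, impute_stacking, table2_profile,
                         tune_classifier)

from conftest import VOL_HI, VOL_LO, make_incomplete, toy_records

SMALL_CONFIG = ImputerConfig(
    k_neighbors=3,
    mice_m=5,
    mice_iterations=5,
    rf_trees=50,
    rf_mtry_grid=(2, 4),
    nn_size_grid=(4,),
    nn_decay_grid=(0.01,),
    svm_c_grid=(1.0,),
    cv_folds=2,
    nn_max_iter=200,
    seed=0,
)


def separable_records(n_per_stratum=12, n_missing=4):
    """Target perfectly determined by deep coma; some target cells masked."""
    coma = ["yes"] * n_per_stratum + ["no"] * n_per_stratum
    target = [VOL_HI] * n_per_stratum + [VOL_LO] * n_per_stratum
    records = toy_records(target, deep_coma=coma,
                          outcome=[1, 0] * n_per_stratum)
    truth = records[TARGET].copy()
    # mask cells from both strata
    masked = list(range(n_missing // 2)) + list(
        range(n_per_stratum, n_per_stratum + n_missing - n_missing // 2))
    records.loc[masked, TARGET] = pd.NA
    return records, truth, masked


class TestMode:
    def test_majority_category_fills_all_cells(self):
        records = toy_records([VOL_LO] * 10 + [VOL_HI] * 3 + [None] * 4)
        completed = impute_mode(make_incomplete(records))
        assert (completed.records[TARGET].tail(4) == VOL_LO).all()

    def test_no_missing_is_identity(self):
        records = toy_records([VOL_LO, VOL_HI, VOL_LO])
        completed = impute_mode(make_incomplete(records))
        assert completed.records.equals(records)

    def test_tie_breaks_to_first_listed_category(self):
        records = toy_records([VOL_LO] * 5 + [VOL_HI] * 5 + [None] * 2)
        completed = impute_mode(make_incomplete(records))
        assert (completed.records[TARGET].tail(2) == VOL_LO).all()

    def test_all_missing_rejected(self):
        records = toy_records([None, None])
        with pytest.raises(ValueError, match="all-missing"):
            impute_mode(make_incomplete(records))


class TestKnn:
    def test_zero_distance_donors_dominate(self):
        # masked record identical to many complete records sharing one value
        records = toy_records(
            [VOL_HI] * 10 + [VOL_LO] * 5 + [None],
            deep_coma=["yes"] * 10 + ["no"] * 5 + ["yes"],
        )
        completed = impute_knn(make_incomplete(records), ImputerConfig())
        assert completed.records[TARGET].iloc[-1] == VOL_HI

    def test_insufficient_complete_records_rejected(self):
        records = toy_records([VOL_LO] * 5 + [None])
        with pytest.raises(ValueError, match="complete records"):
            impute_knn(make_incomplete(records), ImputerConfig())

    def test_median_tie_falls_back_to_overall_mode(self):
        # k=2 forces an exact 0.5 median when the two nearest donors differ
        cfg = ImputerConfig(k_neighbors=2)
        records = toy_records(
            [VOL_HI, VOL_LO] + [VOL_LO] * 8 + [None],
            deep_coma=["yes", "yes"] + ["no"] * 8 + ["yes"],
        )
        completed = impute_knn(make_incomplete(records), cfg)
        # nearest two donors disagree; overall observed mode is "<30 ml"
        assert completed.records[TARGET].iloc[-1] == VOL_LO


class TestMicePmm:
    def test_constant_observed_target_propagates(self):
        records = toy_records([VOL_HI] * 8 + [None] * 3)
        completed = impute_mice_pmm(make_incomplete(records), SMALL_CONFIG)
        assert (completed.records[TARGET].tail(3) == VOL_HI).all()

    def test_separable_target_recovered_exactly(self):
        records, truth, masked = separable_records(12, 4)
        completed = impute_mice_pmm(make_incomplete(records), SMALL_CONFIG)
        assert list(completed.records.loc[masked, TARGET]) == \
            list(truth[masked])

    def test_deterministic_given_seed(self):
        records, *_ = separable_records(12, 4)
        a = impute_mice_pmm(make_incomplete(records), SMALL_CONFIG)
        b = impute_mice_pmm(make_incomplete(records), SMALL_CONFIG)
        pd.testing.assert_frame_equal(a.records, b.records)


class TestTuning:
    def test_lr_has_empty_grid(self):
        records, *_ = separable_records(12, 4)
        tuned = tune_classifier(make_incomplete(records), "LR", SMALL_CONFIG)
        assert tuned.params == {} and tuned.cv_results == []

    def test_single_point_grid_selected(self):
        records, *_ = separable_records(12, 4)
        tuned = tune_classifier(make_incomplete(records), "NN", SMALL_CONFIG)
        assert tuned.params == {"size": 4, "decay": 0.01}

    def test_selected_point_attains_max_recorded_auc(self, coupled_cohort):
        inc = ampute(coupled_cohort, MissingScenario("MCAR", 0.2, 4))
        cfg = ImputerConfig.fast(seed=2)
        tuned = tune_classifier(inc, "RF", cfg)
        recorded = dict(
            (tuple(sorted(p.items())), auc) for p, auc in tuned.cv_results)
        assert recorded[tuple(sorted(tuned.params.items()))] == \
            tuned.best_auc == max(recorded.values())

    def test_recorded_aucs_match_independent_reevaluation(self, coupled_cohort):
        # oracle: rebuild the same folds and estimators with sklearn directly
        inc = ampute(coupled_cohort, MissingScenario("MCAR", 0.2, 4))
        cfg = ImputerConfig.fast(seed=2)
        tuned = tune_classifier(inc, "RF", cfg)
        obs = inc.complete_index
        fm = encode_features(
            inc.records[[c for c in inc.records.columns if c != TARGET]],
            scheme="tree")
        X = fm.matrix[obs]
        cats = table2_profile().variable(TARGET).categories
        y = pd.Categorical(inc.records[TARGET].iloc[obs],
                           categories=list(cats)).codes.astype(int)
        folds = list(StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True,
                                     random_state=tuned.seed).split(X, y))
        for params, recorded_auc in tuned.cv_results:
            aucs = []
            for train, test in folds:
                est = RandomForestClassifier(
                    n_estimators=cfg.rf_trees, max_features=params["mtry"],
                    random_state=tuned.seed).fit(X[train], y[train])
                aucs.append(roc_auc_score(
                    y[test], est.predict_proba(X[test])[:, 1]))
            assert np.mean(aucs) == pytest.approx(recorded_auc, abs=1e-12)

    def test_too_few_minority_cases_for_folds_rejected(self):
        records = toy_records(
            [VOL_HI] * 3 + [VOL_LO] * 20 + [None] * 2,
            deep_coma=["yes"] * 3 + ["no"] * 20 + ["yes"] * 2)
        cfg = ImputerConfig(cv_folds=10)
        with pytest.raises(ValueError, match="stratified folds"):
            tune_classifier(make_incomplete(records), "RF", cfg)


class TestClassifierImputation:
    @pytest.mark.parametrize("method", ["LR", "RF", "NN", "SVM"])
    def test_perfectly_learnable_target_recovered(self, method):
        records, truth, masked = separable_records(12, 4)
        inc = make_incomplete(records)
        tuned = tune_classifier(inc, method, SMALL_CONFIG)
        completed = impute_classifier(inc, tuned, SMALL_CONFIG)
        assert list(completed.records.loc[masked, TARGET]) == \
            list(truth[masked])

    def test_lr_matches_stratum_majority(self):
        # one informative binary predictor; the logit's imputed class is the
        # majority target class within each predictor stratum (closed-form
        # 2x2-table logit)
        coma = ["yes"] * 10 + ["no"] * 10 + ["yes", "no"]
        target = ([VOL_HI] * 8 + [VOL_LO] * 2      # yes-stratum: 80% high
                  + [VOL_HI] * 3 + [VOL_LO] * 7    # no-stratum: 30% high
                  + [None, None])
        records = toy_records(target, deep_coma=coma)
        inc = make_incomplete(records)
        tuned = tune_classifier(inc, "LR", SMALL_CONFIG)
        completed = impute_classifier(inc, tuned, SMALL_CONFIG)
        assert completed.records[TARGET].iloc[-2] == VOL_HI
        assert completed.records[TARGET].iloc[-1] == VOL_LO


class TestStacking:
    def test_meta_features_one_per_first_stage_model(self):
        records, *_ = separable_records(12, 4)
        completed = impute_stacking(make_incomplete(records), SMALL_CONFIG)
        assert sorted(completed.provenance["stage1_params"]) == \
            ["LR", "NN", "RF", "SVM"]

    def test_separable_consensus_recovered(self):
        records, truth, masked = separable_records(12, 4)
        completed = impute_stacking(make_incomplete(records), SMALL_CONFIG)
        assert list(completed.records.loc[masked, TARGET]) == \
            list(truth[masked])

    def test_meta_model_cost_comes_from_grid(self):
        records, *_ = separable_records(12, 4)
        completed = impute_stacking(make_incomplete(records), SMALL_CONFIG)
        assert completed.provenance["meta_C"] in SMALL_CONFIG.svm_c_grid


@pytest.fixture(scope="module")
def incomplete(coupled_cohort):
    return ampute(coupled_cohort, MissingScenario("MCAR", 0.3, 8))


class TestSharedInvariants:
    @pytest.mark.parametrize("method", ["MODE", "KNN", "MICE_PMM", "LR",
                                        "RF", "NN", "SVM", "EL"])
    def test_completed_cohort_is_complete_and_legal(self, incomplete, method):
        cfg = ImputerConfig.fast(seed=5)
        completed = impute(incomplete, method, cfg)
        df = completed.records
        assert not df.isna().any().any()
        legal = set(table2_profile().variable(TARGET).categories)
        assert set(df[TARGET]) <= legal
        # non-target cells never altered
        others = [c for c in df.columns if c != TARGET]
        assert df[others].equals(incomplete.records[others])
        # observed target cells never altered
        obs = incomplete.complete_index
        assert df[TARGET].iloc[obs].equals(
            incomplete.records[TARGET].iloc[obs])

    @pytest.mark.parametrize("method", ["KNN", "MICE_PMM", "RF", "EL"])
    def test_deterministic_under_fixed_seed(self, incomplete, method):
        cfg = ImputerConfig.fast(seed=5)
        a = impute(incomplete, method, cfg)
        b = impute(incomplete, method, cfg)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_unknown_method_rejected(self, incomplete):
        with pytest.raises(ValueError, match="unknown imputation method"):
            impute(incomplete, "EM", ImputerConfig.fast())
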