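"""Cohort generator: profile fidelity, determinism, encoding, CSV I/O."""

import numpy as np
import pandas as pd
import pytest

from imputebench import (OUTCOME, TARGET, GroupProfile, VariableSpec,
                         encode_features, generate_cohort, read_cohort,
                         table2_profile, write_cohort)
from imputebench.cohort import CSV_COLUMNS

from conftest import VOL_HI, VOL_LO, toy_records


class TestProfile:
    def test_group_sizes(self, profile):
        assert profile.n_success == 1207
        assert profile.n_failure == 261
        assert profile.n_total == 1468

    def test_deep_coma_counts(self, profile):
        var = profile.variable("deep_coma")
        assert dict(zip(var.categories, var.success_counts)) == {
            "no": 1190, "yes": 17}
        assert dict(zip(var.categories, var.failure_counts)) == {
            "no": 130, "yes": 131}

    def test_volume_counts(self, profile):
        var = profile.variable(TARGET)
        assert dict(zip(var.categories, var.failure_counts)) == {
            VOL_LO: 128, VOL_HI: 133}
        assert dict(zip(var.categories, var.success_counts)) == {
            VOL_LO: 1032, VOL_HI: 175}

    def test_counts_sum_to_group_sizes(self, profile):
        for var in profile.variables:
            assert sum(var.success_counts) == 1207
            assert sum(var.failure_counts) == 261

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            GroupProfile(
                n_success=10, n_failure=5,
                variables=(VariableSpec("x", ("a", "b"), (9, 2), (3, 2)),),
            )


class TestExactGeneration:
    def test_every_marginal_count_reproduced(self, profile):
        cohort = generate_cohort(profile, mode="exact", seed=3)
        df = cohort.records
        assert len(df) == 1468
        assert (df[OUTCOME] == 1).sum() == 261
        for var in profile.variables:
            for group, counts in (
                (0, var.success_counts), (1, var.failure_counts)
            ):
                sub = df[df[OUTCOME] == group][var.name]
                tab = sub.value_counts()
                for cat, expected in zip(var.categories, counts):
                    assert tab.get(cat, 0) == expected, (var.name, cat)

    def test_no_missing_and_legal_categories(self, profile):
        df = generate_cohort(profile, mode="exact", seed=5).records
        assert not df.isna().any().any()
        for var in profile.variables:
            assert set(df[var.name]) <= set(var.categories)

    def test_same_seed_identical_different_seed_not(self, profile):
        a = generate_cohort(profile, mode="exact", seed=7).records
        b = generate_cohort(profile, mode="exact", seed=7).records
        c = generate_cohort(profile, mode="exact", seed=8).records
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)
        # different permutation, identical marginals
        assert (c[OUTCOME] == 1).sum() == 261

    def test_degenerate_single_category_profile(self):
        prof = GroupProfile(
            n_success=4, n_failure=2,
            variables=tuple(
                VariableSpec(name, (cats[0],), (4,), (2,))
                for name, cats in (
                    (v.name, v.categories) for v in table2_profile().variables
                )
            ),
        )
        df = generate_cohort(prof, mode="exact", seed=0).records
        assert (df.drop(columns=OUTCOME).nunique() == 1).all()

    def test_unknown_mode_rejected(self, profile):
        with pytest.raises(ValueError, match="mode"):
            generate_cohort(profile, mode="bootstrap", seed=0)


class TestStochasticGeneration:
    def test_frequencies_converge_to_profile(self, profile):
        n = 50_000
        df = generate_cohort(profile, mode="stochastic", seed=13,
                             group_sizes=(n, n)).records
        for var in profile.variables:
            for group in (0, 1):
                sub = df[df[OUTCOME] == group][var.name]
                props = var.proportions("success" if group == 0 else "failure")
                for cat, p in zip(var.categories, props):
                    se = np.sqrt(p * (1 - p) / n)
                    observed = (sub == cat).mean()
                    assert abs(observed - p) <= 3 * se + 1e-12, (var.name, cat)

    def test_coupling_induces_within_group_association(self, profile):
        dep = {("deep_coma", TARGET): 2.5}
        df = generate_cohort(profile, mode="stochastic", dependence=dep,
                             seed=17, group_sizes=(8000, 2000)).records
        sub = df[df[OUTCOME] == 0]
        p_hi_coma = (sub[sub["deep_coma"] == "yes"][TARGET] == VOL_HI).mean()
        p_hi_nocoma = (sub[sub["deep_coma"] == "no"][TARGET] == VOL_HI).mean()
        assert p_hi_coma > p_hi_nocoma + 0.1

    def test_nonfinite_coupling_rejected(self, profile):
        with pytest.raises(ValueError, match="finite"):
            generate_cohort(profile, mode="stochastic",
                            dependence={("deep_coma", TARGET): np.inf},
                            seed=0)


class TestEncoding:
    def test_binary_variables_become_single_01_columns(self, profile):
        df = generate_cohort(profile, mode="exact", seed=1).records.head(50)
        fm = encode_features(df, scheme="onehot")
        j = fm.column_index("deep_coma")
        assert len(j) == 1
        assert set(np.unique(fm.matrix[:, j])) <= {0.0, 1.0}

    def test_age_onehot_rows_sum_to_one(self, profile):
        df = generate_cohort(profile, mode="exact", seed=1).records.head(50)
        fm = encode_features(df, scheme="onehot")
        j = fm.column_index("age")
        assert len(j) == 5
        assert np.allclose(fm.matrix[:, j].sum(axis=1), 1.0)

    def test_tree_scheme_is_ordinal(self, profile):
        df = generate_cohort(profile, mode="exact", seed=1).records.head(200)
        fm = encode_features(df, scheme="tree")
        j = fm.column_index("age")
        assert len(j) == 1
        assert set(np.unique(fm.matrix[:, j])) <= {0.0, 1.0, 2.0, 3.0, 4.0}

    def test_target_round_trip(self, profile):
        df = generate_cohort(profile, mode="exact", seed=2).records.head(100)
        for scheme in ("onehot", "tree"):
            fm = encode_features(df, scheme=scheme)
            codes = fm.matrix[:, fm.column_index(TARGET)].ravel()
            decoded = fm.decode_target(codes)
            assert list(decoded) == list(df[TARGET])

    def test_unseen_category_raises(self):
        df = toy_records([VOL_LO, "35 ml"])
        with pytest.raises(ValueError, match="unseen category"):
            encode_features(df, scheme="onehot")


class TestCsvRoundTrip:
    def test_complete_cohort_round_trip(self, profile, tmp_path):
        cohort = generate_cohort(profile, mode="exact", seed=4)
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        pd.testing.assert_frame_equal(back, cohort.records)

    def test_missing_cells_survive_round_trip(self, tmp_path):
        df = toy_records([VOL_LO, None, VOL_HI])
        path = tmp_path / "inc.csv"
        write_cohort(df, path)
        back = read_cohort(path)
        assert back[TARGET].isna().tolist() == [False, True, False]
        assert len(back) == 3

    def test_malformed_file_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("age,gender\n<55,male\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_cohort(path)

    def test_unknown_category_on_read_rejected(self, tmp_path):
        df = toy_records([VOL_LO, VOL_HI])
        path = tmp_path / "bad2.csv"
        write_cohort(df, path)
        text = path.read_text().replace(VOL_HI, "huge")
        path.write_text(text)
        with pytest.raises(ValueError, match="unknown category"):
            read_cohort(path)
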