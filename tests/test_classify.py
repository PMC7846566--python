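"""Z-scoring, PCA contributions, SVM classification, Mann-Whitney U."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata
from sklearn.model_selection import train_test_split

from mpus import classify, synthetic
from mpus.classify import FEATURE_COLUMNS, mann_whitney_u
from mpus.synthetic import effect_size_cohorts, gen_feature_table


def _table_from_matrix(X, cohorts=None):
    df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    df.insert(0, "cohort", cohorts if cohorts is not None else "normal")
    return df


class TestZScore:
    def test_three_point_column_standardizes_to_unit_steps(self):
        # sample-SD convention: {1, 2, 3} -> {-1, 0, 1}
        X = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 6))
        std, _ = classify.zscore(_table_from_matrix(X))
        assert np.allclose(std[FEATURE_COLUMNS].to_numpy()[:, 0], [-1.0, 0.0, 1.0])

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        std, _ = classify.zscore(_table_from_matrix(rng.normal(size=(30, 6))))
        std2, _ = classify.zscore(std)
        assert np.allclose(
            std[FEATURE_COLUMNS].to_numpy(), std2[FEATURE_COLUMNS].to_numpy(), atol=1e-10
        )

    def test_constant_column_rejected_by_name(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 6))
        X[:, 3] = 2.0
        with pytest.raises(ValueError, match="hscan"):
            classify.zscore(_table_from_matrix(X))

    def test_standardizer_applies_training_parameters_to_new_rows(self):
        rng = np.random.default_rng(1)
        train = _table_from_matrix(rng.normal(5.0, 2.0, size=(40, 6)))
        _, std = classify.zscore(train)
        held_out = _table_from_matrix(np.full((3, 6), 5.0))
        out = std.apply(held_out)[FEATURE_COLUMNS].to_numpy()
        expected = (5.0 - std.means.to_numpy()) / std.sds.to_numpy()
        assert np.allclose(out, expected[None, :])


class TestPCAContributions:
    @staticmethod
    def _standardized(seed=0, steps=(1.5, 1.5, 1.5, 6.0, 1.5, 1.5)):
        table = gen_feature_table(
            effect_size_cohorts(steps_sd=steps, n_per_cohort=(39, 12, 12)), seed=seed
        )
        std, _ = classify.zscore(table)
        return std

    def test_contributions_sum_to_hundred(self):
        for k in (1, 2, 3, 6):
            res = classify.pca_contributions(self._standardized(), n_components=k)
            assert res.contributions.sum() == pytest.approx(100.0, abs=1e-8)

    def test_all_components_degenerate_to_uniform(self):
        # with every component retained each standardized feature contributes
        # its full unit variance: 100/6 each
        res = classify.pca_contributions(self._standardized(), n_components=6)
        assert np.allclose(res.contributions.to_numpy(), 100.0 / 6.0, atol=1e-8)

    def test_matches_eigendecomposition_oracle(self):
        std = self._standardized(seed=5)
        X = std[FEATURE_COLUMNS].to_numpy()
        lam, W = np.linalg.eigh(np.cov(X, rowvar=False))
        lam, W = lam[::-1], W[:, ::-1]
        expected = 100.0 * (lam[:3] * W[:, :3] ** 2).sum(axis=1) / lam[:3].sum()
        res = classify.pca_contributions(std, n_components=3)
        assert np.allclose(res.contributions.to_numpy(), expected, atol=1e-8)

    def test_dominant_feature_contributes_above_uniform_share(self):
        for seed in (1, 2, 3):
            res = classify.pca_contributions(self._standardized(seed=seed), 3)
            assert res.contributions["hscan"] > 100.0 / 6.0

    def test_requires_standardized_input(self):
        table = gen_feature_table(effect_size_cohorts(), seed=0)
        with pytest.raises(ValueError, match="Z-scored"):
            classify.pca_contributions(table, 3)

    def test_component_sign_convention(self):
        res = classify.pca_contributions(self._standardized(), 3)
        for k in range(3):
            j = int(np.argmax(np.abs(res.loadings[:, k])))
            assert res.loadings[j, k] > 0


class TestSVM:
    def test_well_separated_cohorts_classify_perfectly(self):
        table = gen_feature_table(effect_size_cohorts((3.0,) * 6, (39, 12)), seed=1)
        report = classify.svm_train_eval(table, "two_category", "raw_features", 0.8, seed=1)
        assert report.test_accuracy == 100.0
        assert report.overall_accuracy == 100.0

    def test_permuted_labels_fall_to_chance(self):
        table = gen_feature_table(effect_size_cohorts((3.0,) * 6, (26, 13)), seed=2)
        rng = np.random.default_rng(0)
        majority = 2.0 / 3.0
        accs = []
        for _ in range(15):
            shuffled = table.copy()
            shuffled["cohort"] = rng.permutation(shuffled["cohort"].to_numpy())
            try:
                rep = classify.svm_train_eval(shuffled, "two_category", "raw_features", 0.8, seed=0)
            except ValueError:
                continue
            accs.append(rep.test_accuracy / 100.0)
        # mean permuted accuracy within binomial noise of the majority rate
        n_test = int(np.ceil(0.2 * len(table)))
        se = np.sqrt(majority * (1 - majority) / (n_test * len(accs)))
        assert abs(np.mean(accs) - majority) < 5 * se

    def test_conflicting_duplicate_labels_are_inseparable(self):
        rng = np.random.default_rng(3)
        X = np.tile(rng.normal(size=(10, 6)), (2, 1))
        cohorts = ["normal"] * 10 + ["high_fat"] * 10
        table = _table_from_matrix(X, cohorts)
        report = classify.svm_train_eval(table, "two_category", "raw_features", 0.8, seed=0)
        assert report.overall_accuracy < 100.0

    def test_split_determinism(self):
        table = gen_feature_table(effect_size_cohorts((1.0,) * 6, (39, 12)), seed=4)
        a = classify.svm_train_eval(table, "two_category", "raw_features", 0.8, seed=9)
        b = classify.svm_train_eval(table, "two_category", "raw_features", 0.8, seed=9)
        assert a == b

    def test_three_category_modes_and_pc_spaces(self):
        table = gen_feature_table(effect_size_cohorts((3.0,) * 6, (39, 12, 12)), seed=5)
        for space in ("first_3_pcs", "all_pcs"):
            rep = classify.svm_train_eval(table, "three_category", space, 0.8, seed=0)
            assert rep.classes == ("high_fat", "low_fat", "normal")
            assert rep.test_accuracy >= 90.0

    def test_no_leakage_from_test_rows(self):
        # perturbing only the (reproducible) test split leaves the fitted
        # model and its training accuracy unchanged
        table = gen_feature_table(effect_size_cohorts((2.0,) * 6, (39, 12)), seed=6)
        sub = table[table["cohort"].isin(["normal", "high_fat"])].reset_index(drop=True)
        idx = np.arange(len(sub))
        tr, te = train_test_split(
            idx, train_size=0.8, stratify=sub["cohort"], random_state=0
        )
        base = classify.svm_train_eval(sub, "two_category", "raw_features", 0.8, seed=0)
        mutated = sub.copy()
        mutated.loc[te, FEATURE_COLUMNS] = (
            mutated.loc[te, FEATURE_COLUMNS].to_numpy() + 100.0
        )
        alt = classify.svm_train_eval(mutated, "two_category", "raw_features", 0.8, seed=0)
        assert alt.train_accuracy == base.train_accuracy
        assert alt.best_params == base.best_params

    def test_cohort_size_validation(self):
        table = _table_from_matrix(np.random.default_rng(0).normal(size=(5, 6)),
                                   ["normal"] * 4 + ["high_fat"])
        with pytest.raises(ValueError, match=">= 2 rows"):
            classify.svm_train_eval(table, "two_category")


def _enumeration_p(x, y):
    """Brute-force two-sided exact p over all C(n, n_x) rank assignments.

    Two-sided under the U = min(U_x, U_y) convention: the fraction of
    labelings whose min-U is at most the observed one (equivalently, twice
    the lower tail of the U_x distribution, by symmetry).
    """
    combined = np.concatenate([x, y])
    n_x = len(x)
    ranks = rankdata(combined)

    def u_min(ix):
        r_x = ranks[list(ix)].sum()
        u_x = r_x - n_x * (n_x + 1) / 2
        return min(u_x, n_x * len(y) - u_x)

    observed = u_min(range(n_x))
    us = [u_min(ix) for ix in itertools.combinations(range(len(combined)), n_x)]
    return min(1.0, float(np.mean([u <= observed for u in us])))


class TestMannWhitney:
    def test_textbook_example(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.u == 0.0
        assert res.p == pytest.approx(1.0 / 3.0)
        assert not res.significant

    def test_identical_samples_not_significant(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == pytest.approx(1.0)
        assert res.method == "asymptotic"  # ties present

    def test_clear_shift_is_significant(self):
        res = mann_whitney_u(np.arange(6) + 100.0, np.arange(6.0))
        assert res.p < 0.05 and res.significant

    @pytest.mark.parametrize("n_x,n_y", [(1, 4), (2, 2), (3, 5), (4, 4), (5, 3)])
    def test_exact_p_matches_enumeration(self, n_x, n_y):
        rng = np.random.default_rng(n_x * 10 + n_y)
        values = rng.permutation(np.arange(n_x + n_y, dtype=float))
        x, y = values[:n_x], values[n_x:]
        res = mann_whitney_u(x, y)
        assert res.method == "exact"
        assert res.p == pytest.approx(_enumeration_p(x, y), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        st.lists(st.integers(0, 1000), min_size=1, max_size=6),
        st.lists(st.integers(0, 1000), min_size=1, max_size=6),
    )
    def test_exact_path_property(self, xs, ys):
        x = np.asarray(xs, dtype=float)
        y = np.asarray(ys, dtype=float) + 0.5  # break cross-sample ties
        if len(np.unique(np.concatenate([x, y]))) < len(x) + len(y):
            return  # within-sample ties: asymptotic path, not checked here
        res = mann_whitney_u(x, y)
        assert res.p == pytest.approx(_enumeration_p(x, y), abs=1e-12)
        assert 0.0 < res.p <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])
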