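"""Summary vectors, reference tables, LDA augmentation, RF model choice."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitostruct import coalescent as co
from mitostruct.abc_rf import (
    ModelChoiceForest,
    ReferenceTable,
    SummaryStatVector,
    augment_with_lda,
    build_reference_table,
    feature_names,
    summary_vector,
    train_and_select,
)
from mitostruct.seq_io import Alignment, GroupedAlignment


def _grouped(seq_a, seq_b):
    ids_a = tuple(f"a{i}" for i in range(len(seq_a)))
    ids_b = tuple(f"b{i}" for i in range(len(seq_b)))
    aln = Alignment(ids=ids_a + ids_b, sequences=tuple(seq_a) + tuple(seq_b))
    return GroupedAlignment(
        alignment=aln, partition={"A": ids_a, "B": ids_b}
    )


class TestSummaryVector:
    def test_monomorphic_identical_groups(self):
        ga = _grouped(["ACGT"] * 4, ["ACGT"] * 5)
        vec = summary_vector(ga)
        np.testing.assert_allclose(
            vec.values, [1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0]
        )
        assert vec.d_imputed == (True, True)

    def test_matches_direct_module_calls(self):
        rng = np.random.default_rng(4)
        ga, _ = co.simulate_dataset(
            "continuity",
            co.default_priors("continuity"),
            co.SamplingConfig(n_a=5, age_a=3500, n_b=6, age_b=2450),
            rng=rng,
            L=3000,
        )
        from mitostruct.differentiation import (
            grouped_difference_matrix,
            pairwise_fst,
        )
        from mitostruct.diversity import tajimas_d, within_group_stats

        vec = summary_vector(ga)
        a = within_group_stats(ga.group_alignment(ga.group_labels[0]).sequences)
        assert vec.values[0] == a.K
        assert vec.values[2] == a.S
        assert vec.values[3] == pytest.approx(
            tajimas_d(a.S, a.Pi, a.n) if a.S else 0.0
        )
        fst = pairwise_fst(grouped_difference_matrix(ga), ga.partition)
        assert vec.values[-1] == pytest.approx(fst.values[0, 1])

    def test_group_count_enforced(self):
        ga = _grouped(["ACGT"] * 2, ["ACGT"] * 2)
        three = GroupedAlignment(
            alignment=ga.alignment,
            partition={"A": ("a0",), "B": ("a1",), "C": ("b0", "b1")},
        )
        with pytest.raises(ValueError):
            summary_vector(three)

    def test_finite_over_random_prior_draws(self):
        priors = co.default_priors("discontinuity")
        samp = co.SamplingConfig()
        table = build_reference_table(
            {"discontinuity": priors}, samp, 150, seed=6, L=2000
        )
        assert np.isfinite(table.X).all()


class TestReferenceTable:
    def test_balanced_and_reproducible(self):
        priors = {
            t: co.default_priors(t) for t in ("continuity", "discontinuity")
        }
        samp = co.SamplingConfig()
        t1 = build_reference_table(priors, samp, 100, seed=5, L=2000)
        t2 = build_reference_table(priors, samp, 100, seed=5, L=2000)
        assert t1.X.shape == (200, 11)
        assert (t1.labels == "continuity").sum() == 100
        np.testing.assert_array_equal(t1.X, t2.X)
        pd.testing.assert_frame_equal(t1.params, t2.params)

    def test_separated_priors_separate_summary_distributions(self):
        small = co.PriorSet(
            "continuity",
            {
                "n_anc": co.Prior("loguniform", 100, 150),
                "mu": co.Prior("loguniform", 1e-8, 1.2e-8),
            },
        )
        big = co.PriorSet(
            "continuity",
            {
                "n_anc": co.Prior("loguniform", 8000, 12000),
                "mu": co.Prior("loguniform", 4e-8, 5e-8),
            },
        )
        table = build_reference_table(
            {"small": small, "big": big}, co.SamplingConfig(), 150, seed=9, L=3000
        )
        s_col = table.feature_names.index("S_bronze_age")
        ks = stats.ks_2samp(
            table.X[table.labels == "small", s_col],
            table.X[table.labels == "big", s_col],
        )
        assert ks.pvalue < 1e-3


class TestLda:
    def _table_from_blobs(self, rng, shift, n=2000):
        X = rng.normal(size=(2 * n, 11))
        X[n:, 4] += shift  # separation on feature index 4 only
        labels = np.array(["m1"] * n + ["m2"] * n)
        return ReferenceTable(
            X=X, labels=labels, params=pd.DataFrame(), feature_names=feature_names()
        )

    def test_axis_aligns_with_separating_feature(self):
        rng = np.random.default_rng(2)
        table = self._table_from_blobs(rng, shift=6.0)
        obs = SummaryStatVector(values=np.zeros(11), names=feature_names())
        _, _, lda = augment_with_lda(table, obs)
        axis = lda.scalings_[:, 0]
        cos = abs(axis[4]) / np.linalg.norm(axis)
        assert cos > 0.99

    def test_identical_classes_project_to_same_mean(self):
        rng = np.random.default_rng(3)
        table = self._table_from_blobs(rng, shift=0.0)
        obs = SummaryStatVector(values=np.zeros(11), names=feature_names())
        X_aug, _, _ = augment_with_lda(table, obs)
        proj = X_aug[:, -1]
        m1 = proj[table.labels == "m1"].mean()
        m2 = proj[table.labels == "m2"].mean()
        pooled_sd = proj.std()
        assert abs(m1 - m2) < 0.5 * pooled_sd

    def test_observation_projection_invariant_to_row_order(self):
        rng = np.random.default_rng(4)
        table = self._table_from_blobs(rng, shift=4.0)
        obs = SummaryStatVector(values=rng.normal(size=11), names=feature_names())
        _, obs_aug1, _ = augment_with_lda(table, obs)
        order = rng.permutation(table.X.shape[0])
        shuffled = ReferenceTable(
            X=table.X[order],
            labels=table.labels[order],
            params=pd.DataFrame(),
            feature_names=table.feature_names,
        )
        _, obs_aug2, _ = augment_with_lda(shuffled, obs)
        assert obs_aug1[-1] == pytest.approx(obs_aug2[-1], abs=1e-8)


@pytest.fixture(scope="module")
def small_table():
    priors = {
        t: co.default_priors(t) for t in ("continuity", "discontinuity")
    }
    return build_reference_table(
        priors, co.SamplingConfig(), 250, seed=12, L=4000
    )


class TestModelChoice:
    def test_votes_sum_to_n_trees(self, small_table):
        obs = SummaryStatVector(
            values=small_table.X[0], names=small_table.feature_names
        )
        res = train_and_select(small_table, obs, n_trees=150, seed=1)
        assert sum(res.votes.values()) == 150
        assert res.selected in res.votes
        assert 0.0 <= res.posterior_probability <= 1.0

    def test_confusion_rows_sum_to_per_model_counts(self, small_table):
        forest = ModelChoiceForest(small_table, n_trees=150, seed=2)
        conf = forest.oob_confusion
        assert conf.to_numpy().sum() == small_table.X.shape[0]
        for mdl in ("continuity", "discontinuity"):
            assert conf.loc[mdl].sum() == 250

    def test_result_serialisable(self, small_table):
        obs = SummaryStatVector(
            values=small_table.X[-1], names=small_table.feature_names
        )
        res = train_and_select(small_table, obs, n_trees=150, seed=3)
        import json

        blob = json.dumps(res.to_dict())
        assert "posterior_probability" in blob

    def test_minimum_tree_count_enforced(self, small_table):
        with pytest.raises(ValueError):
            ModelChoiceForest(small_table, n_trees=50)
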