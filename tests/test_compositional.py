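"""Log-ratio machinery, distances, ordination, PERMANOVA, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acetotrace.compositional import (
    FeatureTable,
    aitchison_distance,
    clr,
    group_test,
    log_ratio,
    ordinate,
    pathway_aggregate,
    permanova,
    rpk_normalize,
    wilcoxon_rank_sum,
)
from acetotrace.simulate import CommunitySimSpec, generate_count_tables

import _oracles


def table_from(counts: dict, samples=None, **meta) -> FeatureTable:
    df = pd.DataFrame(counts, index=samples or [f"s{i}" for i in range(len(next(iter(counts.values()))))])
    fmeta = pd.DataFrame(meta, index=df.columns) if meta else None
    return FeatureTable(df, fmeta)


class TestRpk:
    def test_definition_and_identity_length(self):
        table = table_from({"a": [500.0], "b": [7.0]}, length_bp=[2000, 1000])
        rpk = rpk_normalize(table)
        assert rpk.counts.loc["s0", "a"] == pytest.approx(250.0)
        assert rpk.counts.loc["s0", "b"] == pytest.approx(7.0)

    def test_doubling_lengths_halves_values(self):
        t1 = table_from({"a": [10.0, 20.0]}, samples=["x", "y"], length_bp=[500])
        t2 = table_from({"a": [10.0, 20.0]}, samples=["x", "y"], length_bp=[1000])
        np.testing.assert_allclose(
            rpk_normalize(t2).counts.to_numpy(), rpk_normalize(t1).counts.to_numpy() / 2
        )

    def test_annotations_preserved(self):
        table = table_from({"a": [1.0]}, length_bp=[100], gene=["rpoA"])
        assert rpk_normalize(table).feature_meta["gene"].tolist() == ["rpoA"]


class TestLogRatio:
    def test_hand_computation(self):
        table = table_from({"num": [80.0], "den": [20.0]})
        series = log_ratio(table, ["num"], ["den"])
        assert series.values.iloc[0] == pytest.approx(np.log(4.0), abs=1e-12)

    def test_identity_ratio_is_zero(self):
        table = table_from({"a": [5.0, 9.0], "b": [2.0, 3.0]}, samples=["x", "y"])
        series = log_ratio(table, ["a", "b"], ["a", "b"], allow_overlap=True)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-12)

    def test_depth_invariance(self):
        counts = pd.DataFrame(
            {"a": [80.0, 8.0], "b": [20.0, 2.0]}, index=["x", "y"]
        )
        base = log_ratio(FeatureTable(counts), ["a"], ["b"]).values
        scaled = log_ratio(FeatureTable(counts * [10.0, 3.0][0]), ["a"], ["b"]).values
        np.testing.assert_allclose(base, scaled, atol=1e-12)

    def test_zero_denominator_excluded_and_reported(self):
        table = table_from({"a": [5.0, 5.0], "b": [2.0, 0.0]}, samples=["x", "y"])
        series = log_ratio(table, ["a"], ["b"])
        assert series.excluded_samples == ("y",)
        assert list(series.values.index) == ["x"]

    def test_overlap_rejected(self):
        table = table_from({"a": [1.0], "b": [1.0]})
        with pytest.raises(ValueError, match="overlap"):
            log_ratio(table, ["a", "b"], ["b"])


class TestWilcoxon:
    def test_extreme_arrangement_exact_p(self):
        stat, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_tie_policy(self):
        _, p = wilcoxon_rank_sum([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_rank_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=5)
        y = rng.normal(0.5, size=5)
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(_oracles.exact_rank_sum_p(x, y), abs=1e-12)

    def test_group_test_pairs_and_adjustment(self):
        values = pd.Series(
            [1, 2, 3, 4, 10, 11, 12, 13, 20, 21, 22, 23],
            index=[f"s{i}" for i in range(12)],
        )
        groups = pd.Series(["a"] * 4 + ["b"] * 4 + ["c"] * 4, index=values.index)
        out = group_test(values, groups)
        assert len(out) == 3
        assert (out["p_adjusted"] >= out["p_value"] - 1e-15).all()
        tukey = group_test(values, groups, adjust="tukey-hsd")
        assert len(tukey) == 3

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            group_test(pd.Series([1.0, 2.0, 3.0]), pd.Series(["a", "a", "b"]))


class TestAitchison:
    def test_identical_rows_distance_zero(self):
        table = table_from({"a": [3.0, 3.0], "b": [7.0, 7.0]}, samples=["x", "y"])
        d = aitchison_distance(table, pseudocount=0)
        assert d.loc["x", "y"] == pytest.approx(0.0, abs=1e-12)

    def test_two_part_closed_form(self):
        a, b = 0.2, 0.7
        table = table_from({"p": [a, b], "q": [1 - a, 1 - b]}, samples=["x", "y"])
        d = aitchison_distance(table, pseudocount=0).loc["x", "y"]
        # CLR of (a, 1-a) is +/- 0.5*ln(a/(1-a)); Euclidean distance follows
        expected = np.sqrt(2) * abs(np.log(a / (1 - a)) - np.log(b / (1 - b))) / 2
        assert d == pytest.approx(expected, abs=1e-12)

    def test_perturbation_invariance(self):
        rng = np.random.default_rng(0)
        comp = rng.dirichlet(np.ones(6), size=3)
        perturb = rng.gamma(2.0, size=6)
        d1 = aitchison_distance(FeatureTable(pd.DataFrame(comp)), pseudocount=0)
        d2 = aitchison_distance(FeatureTable(pd.DataFrame(comp * perturb)), pseudocount=0)
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        comp = rng.gamma(3.0, size=(4, 5))
        depths = rng.uniform(0.5, 20.0, size=(4, 1))
        d1 = aitchison_distance(FeatureTable(pd.DataFrame(comp)), pseudocount=0)
        d2 = aitchison_distance(FeatureTable(pd.DataFrame(comp * depths)), pseudocount=0)
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-12)

    def test_matches_skbio_clr(self):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        rng = np.random.default_rng(2)
        comp = rng.gamma(3.0, size=(3, 6))
        np.testing.assert_allclose(clr(comp), skbio_comp.clr(comp), atol=1e-10)

    def test_metric_properties(self):
        rng = np.random.default_rng(3)
        table = FeatureTable(pd.DataFrame(rng.gamma(2.0, size=(5, 7))))
        d = aitchison_distance(table, pseudocount=0).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-10


class TestOrdination:
    def test_dense_limit_equals_clr_pca(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.gamma(5.0, size=(8, 10)) + 1.0)
        res = ordinate(FeatureTable(counts), rank=2)
        X = clr(counts.to_numpy())
        X = X - X.mean(axis=0, keepdims=True)
        _, s, _ = np.linalg.svd(X, full_matrices=False)
        np.testing.assert_allclose(
            res.proportion_explained.to_numpy(), (s**2 / (s**2).sum())[:2], atol=1e-10
        )

    def test_planted_axis_separates_groups(self):
        spec = CommunitySimSpec(seed=11)
        abundance, _, meta = generate_count_tables(spec)
        res = ordinate(abundance, rank=2)
        pc1 = res.samples["PC1"]
        g = meta["group"] == "ethanol"
        # planted log-fold-change axis shows up as a group shift on PC1
        lo, hi = sorted([pc1[g].mean(), pc1[~g].mean()])
        assert hi - lo > pc1.std() * 0.5

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.poisson(20.0, size=(6, 9)).astype(float),
            index=[f"s{i}" for i in range(6)],
        )
        perm = [3, 1, 5, 0, 2, 4]
        res1 = ordinate(FeatureTable(counts), rank=2)
        res2 = ordinate(FeatureTable(counts.iloc[perm]), rank=2)
        np.testing.assert_allclose(
            res1.samples.iloc[perm].to_numpy(), res2.samples.to_numpy(), atol=1e-6
        )

    def test_reconstruction_error_non_increasing_in_rank(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(rng.gamma(4.0, size=(7, 12)) + 0.5)
        X = clr(counts.to_numpy())
        X = X - X.mean(axis=0, keepdims=True)
        errs = []
        for rank in (1, 2, 3):
            res = ordinate(FeatureTable(counts), rank=rank)
            approx = res.samples.to_numpy() @ res.features.to_numpy().T
            errs.append(np.linalg.norm(X - approx))
        assert errs[0] >= errs[1] >= errs[2]

    def test_invalid_rank_rejected(self):
        table = FeatureTable(pd.DataFrame(np.ones((3, 4))))
        with pytest.raises(ValueError, match="rank"):
            ordinate(table, rank=3)


class TestPermanova:
    def test_no_structure_exhaustive_p_is_one(self):
        d = np.ones((6, 6)) - np.eye(6)
        res = permanova(d, ["a"] * 3 + ["b"] * 3, exhaustive=True)
        assert res.p_value == pytest.approx(1.0)

    def test_sampled_agrees_with_exhaustive(self):
        rng = np.random.default_rng(8)
        pts = np.vstack([rng.normal(0, 1, (3, 4)), rng.normal(2.0, 1, (3, 4))])
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        groups = ["a"] * 3 + ["b"] * 3
        exact = permanova(d, groups, exhaustive=True)
        f_oracle, p_oracle = _oracles.exhaustive_permanova_p(d, groups)
        assert exact.pseudo_F == pytest.approx(f_oracle, abs=1e-10)
        assert exact.p_value == pytest.approx(p_oracle, abs=1e-12)
        sampled = permanova(d, groups, n_permutations=4999, seed=1)
        assert abs(sampled.p_value - exact.p_value) < 0.05

    def test_matches_skbio(self, community):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        abundance, _, meta = community
        d = aitchison_distance(abundance)
        res = permanova(d, meta["group"], n_permutations=999, seed=0)
        dm = skbio_distance.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        ref = skbio_distance.permanova(dm, meta["group"].to_numpy(), permutations=999)
        assert res.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-8)
        assert abs(res.p_value - ref["p-value"]) < 0.05

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            permanova(np.arange(9.0).reshape(3, 3), ["a", "a", "b"])


class TestPathwayAggregate:
    def test_pass_through_single_gene(self):
        expr = pd.DataFrame({"g1": [5.0, 6.0]}, index=["x", "y"])
        pmap = pd.DataFrame({"feature": ["g1"], "reaction": ["r1"], "pathway": ["P"]})
        out = pathway_aggregate(expr, pmap)
        np.testing.assert_allclose(out.loc["P"], [5.0, 6.0])

    def test_multicopy_max_then_pathway_mean(self):
        expr = pd.DataFrame(
            {"g1": [3.0], "g2": [7.0], "g3": [2.0], "g4": [4.0]}, index=["x"]
        )
        pmap = pd.DataFrame(
            {
                "feature": ["g1", "g2", "g3", "g4"],
                "reaction": ["r1", "r1", "r2", "r2"],
                "pathway": ["P", "P", "P", "P"],
            }
        )
        out = pathway_aggregate(expr, pmap)
        # r1 = max(3, 7) = 7; r2 = max(2, 4) = 4; P = mean(7, 4)
        assert out.loc["P", "x"] == pytest.approx(5.5)

    def test_reaction_mean_example(self):
        expr = pd.DataFrame({"g1": [2.0], "g2": [4.0]}, index=["x"])
        pmap = pd.DataFrame(
            {"feature": ["g1", "g2"], "reaction": ["r1", "r2"], "pathway": ["P"] * 2}
        )
        assert pathway_aggregate(expr, pmap).loc["P", "x"] == pytest.approx(3.0)

    def test_unknown_feature_rejected(self):
        expr = pd.DataFrame({"g1": [2.0]}, index=["x"])
        pmap = pd.DataFrame({"feature": ["nope"], "reaction": ["r"], "pathway": ["P"]})
        with pytest.raises(ValueError, match="absent"):
            pathway_aggregate(expr, pmap)


@given(st.integers(0, 1000))
@settings(max_examples=20, deadline=None)
def test_logratio_scale_invariance_property(seed):
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(rng.gamma(2.0, size=(3, 5)) + 0.01)
    scales = rng.uniform(0.1, 50.0, size=(3, 1))
    cols = list(counts.columns)
    base = log_ratio(FeatureTable(counts), cols[:2], cols[2:]).values
    scaled = log_ratio(FeatureTable(counts * scales), cols[:2], cols[2:]).values
    np.testing.assert_allclose(base, scaled, atol=1e-12)
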