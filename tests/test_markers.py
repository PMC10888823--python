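"""Mean Ratio / one-vs-all statistics and marker-set construction rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import deconvbench as db
from deconvbench.data_model import DataModelError
from deconvbench.markers import TypeMeans


def brute_force_mean_ratio(means, types, genes, target):
    """Independent double loop over non-target types."""
    out = {}
    ti = types.index(target)
    for gi, g in enumerate(genes):
        best, best_type = -1.0, None
        for k, ct in enumerate(types):
            if k == ti:
                continue
            if means[k, gi] > best:
                best, best_type = means[k, gi], ct
        t = means[ti, gi]
        if best > 0:
            ratio = t / best
        else:
            ratio = np.inf if t > 0 else 0.0
        out[g] = (ratio, best_type)
    return out


def _means_from_dict(d, genes):
    types = list(d)
    mat = np.array([[d[ct][g] for g in genes] for ct in types])
    return TypeMeans(mat, types, genes)


class TestTypeMeans:
    def test_simple_mean(self):
        expr = db.ExpressionMatrix(np.array([[2.0, 4.0]]), ["g"], ["c1", "c2"],
                                   scale="cpm")
        ann = db.CellAnnotation(["c1", "c2"], ["A", "A"])
        tm = db.type_means(expr, ann)
        assert tm.values[0, 0] == 3.0

    def test_matches_per_type_per_gene_loop(self):
        rng = np.random.default_rng(21)
        vals = rng.random((100, 60)) * 10
        expr = db.ExpressionMatrix(vals, [f"g{i}" for i in range(100)],
                                   [f"c{i}" for i in range(60)], scale="cpm")
        labels = [f"T{i % 4}" for i in range(60)]
        ann = db.CellAnnotation(expr.unit_ids, labels)
        tm = db.type_means(expr, ann)
        for k, ct in enumerate(tm.cell_type_ids):
            idx = [i for i, lab in enumerate(labels) if lab == ct]
            for gi in range(0, 100, 17):
                assert tm.values[k, gi] == pytest.approx(
                    np.mean([vals[gi, i] for i in idx]))

    def test_empty_cell_type_rejected(self):
        expr = db.ExpressionMatrix(np.ones((2, 2)), ["g1", "g2"],
                                   ["c1", "c2"], scale="cpm")
        ann = db.CellAnnotation(["c1", "c3"], ["A", "B"])
        with pytest.raises(DataModelError):
            db.type_means(expr, ann)


class TestMeanRatio:
    def test_direct_formula_and_second_type(self):
        tm = _means_from_dict({"A": {"g": 6.0}, "B": {"g": 3.0},
                               "C": {"g": 2.0}}, ["g"])
        res = db.mean_ratio(tm, "A")
        assert res.loc["g", "mean_ratio"] == 2.0
        assert res.loc["g", "second_type"] == "B"

    def test_zero_nontarget_max_gives_infinity(self):
        tm = _means_from_dict({"A": {"g": 5.0}, "B": {"g": 0.0},
                               "C": {"g": 0.0}}, ["g"])
        res = db.mean_ratio(tm, "A")
        assert np.isinf(res.loc["g", "mean_ratio"])

    def test_all_zero_gene_gets_ratio_zero(self):
        tm = _means_from_dict({"A": {"g": 0.0}, "B": {"g": 0.0}}, ["g"])
        assert db.mean_ratio(tm, "A").loc["g", "mean_ratio"] == 0.0

    def test_matches_brute_force_on_random_means(self):
        rng = np.random.default_rng(22)
        genes = [f"g{i:03d}" for i in range(300)]
        types = ["A", "B", "C", "D", "E"]
        mat = rng.random((5, 300)) * 5
        mat[rng.random(mat.shape) < 0.1] = 0.0
        tm = TypeMeans(mat, types, genes)
        for target in types:
            res = db.mean_ratio(tm, target)
            oracle = brute_force_mean_ratio(mat, types, genes, target)
            for g in genes:
                exp_ratio, _ = oracle[g]
                assert res.loc[g, "mean_ratio"] == pytest.approx(exp_ratio)
            # ranks are a permutation ordered by (ratio desc, mean desc, id)
            assert sorted(res["rank_ratio"]) == list(range(1, 301))
            ordered = res.sort_values("rank_ratio")
            r = ordered["mean_ratio"].to_numpy()
            assert np.all(r[:-1] >= r[1:])

    def test_scale_invariance_under_common_positive_factor(self):
        rng = np.random.default_rng(23)
        mat = rng.random((4, 50)) + 0.01
        tm1 = TypeMeans(mat, list("ABCD"), [f"g{i}" for i in range(50)])
        tm2 = TypeMeans(mat * 7.3, list("ABCD"), [f"g{i}" for i in range(50)])
        r1 = db.mean_ratio(tm1, "B")
        r2 = db.mean_ratio(tm2, "B")
        assert np.allclose(r1["mean_ratio"], r2["mean_ratio"])
        assert (r1["rank_ratio"] == r2["rank_ratio"]).all()

    def test_two_type_reciprocity(self):
        rng = np.random.default_rng(24)
        mat = rng.random((2, 30)) + 0.05
        tm = TypeMeans(mat, ["A", "B"], [f"g{i}" for i in range(30)])
        ra = db.mean_ratio(tm, "A")["mean_ratio"].to_numpy()
        rb = db.mean_ratio(tm, "B")["mean_ratio"].to_numpy()
        assert np.allclose(ra, 1.0 / rb)

    def test_unknown_target_rejected(self):
        tm = _means_from_dict({"A": {"g": 1.0}, "B": {"g": 1.0}}, ["g"])
        with pytest.raises(DataModelError):
            db.mean_ratio(tm, "Z")


class TestOneVsAll:
    def _expr(self, vals, labels):
        expr = db.ExpressionMatrix(np.asarray(vals, dtype=float),
                                   [f"g{i}" for i in range(len(vals))],
                                   [f"c{i}" for i in range(len(labels))],
                                   scale="log")
        return expr, db.CellAnnotation(expr.unit_ids, labels)

    def test_identical_constant_groups_give_t0_p1(self):
        expr, ann = self._expr([[2.0, 2.0, 2.0, 2.0]], ["A", "A", "B", "B"])
        res = db.one_vs_all(expr, ann, "A")
        assert res.loc["g0", "t_stat"] == 0.0
        assert res.loc["g0", "p_value"] == 1.0

    def test_constant_unequal_groups_flagged_with_p0(self):
        expr, ann = self._expr([[4.0, 4.0, 0.0, 0.0]], ["A", "A", "B", "B"])
        res = db.one_vs_all(expr, ann, "A")
        assert res.loc["g0", "logFC_1vall"] == 4.0
        assert res.loc["g0", "p_value"] == 0.0
        assert bool(res.loc["g0", "degenerate"])

    def test_matches_scipy_welch_per_gene(self):
        rng = np.random.default_rng(25)
        vals = rng.normal(size=(200, 40))
        labels = ["A"] * 12 + ["B"] * 18 + ["C"] * 10
        expr = db.ExpressionMatrix(vals, [f"g{i}" for i in range(200)],
                                   [f"c{i}" for i in range(40)], scale="log")
        ann = db.CellAnnotation(expr.unit_ids, labels)
        res = db.one_vs_all(expr, ann, "A")
        x, y = vals[:, :12], vals[:, 12:]
        t_ref, p_ref = sps.ttest_ind(x, y, axis=1, equal_var=False)
        assert np.allclose(res["t_stat"], t_ref)
        assert np.allclose(res["p_value"], p_ref)

    def test_small_group_rejected_naming_the_group(self):
        expr, ann = self._expr([[1.0, 2.0, 3.0]], ["A", "B", "B"])
        with pytest.raises(DataModelError, match="'A'"):
            db.one_vs_all(expr, ann, "A")


class TestBuildMarkerSets:
    def _stats(self, per_type):
        rows = []
        for ct, genes in per_type.items():
            ranked = sorted(genes.items(), key=lambda kv: (-kv[1], kv[0]))
            for rank, (g, ratio) in enumerate(ranked, start=1):
                rows.append({"gene": g, "cell_type": ct, "mean_ratio": ratio,
                             "rank_ratio": rank, "rank_fc": rank,
                             "logFC_1vall": ratio})
        return pd.DataFrame(rows)

    def test_top_n_saturates_at_gene_count(self):
        stats = self._stats({"A": {"g1": 3.0, "g2": 2.0, "g3": 0.5}})
        sets = db.build_marker_sets(stats, "mean_ratio_top_n", {"n": 10})
        assert sets.sets["A"] == ["g1", "g2", "g3"]

    def test_top_n_intersected_with_common_after_ranking(self):
        stats = self._stats({"A": {"g1": 3.0, "g2": 2.0, "g3": 1.5}})
        sets = db.build_marker_sets(stats, "mean_ratio_top_n", {"n": 2},
                                    common_genes={"g2", "g3"})
        # g1 ranks in the top 2 but is not common; the set shrinks below N
        assert sets.sets["A"] == ["g2"]

    def test_over_threshold_rule(self):
        stats = self._stats({"A": {"g1": 3.0, "g2": 1.5, "g3": 0.8}})
        sets = db.build_marker_sets(stats, "mean_ratio_over_t", {"t": 2.0})
        assert sets.sets["A"] == ["g1"]

    def test_mad_rule_strict_inequality(self):
        stats = self._stats({"A": {f"g{i}": 2.0 for i in range(4)} | {"g9": 10.0}})
        sets = db.build_marker_sets(stats, "mean_ratio_mad_k", {"k": 3.0})
        # ratios {2,2,2,2,10}: median 2, MAD 0 -> threshold 2, strictly above
        assert sets.sets["A"] == ["g9"]

    def test_mad_rule_empty_pool_warns_not_errors(self):
        stats = self._stats({"A": {"g1": 0.5, "g2": 0.9}})
        sets = db.build_marker_sets(stats, "mean_ratio_mad_k", {"k": 3.0})
        assert sets.sets["A"] == []
        assert sets.warnings

    def test_one_vs_all_top_n_uses_fold_change_rank(self):
        stats = self._stats({"A": {"g1": 3.0, "g2": 2.0, "g3": 1.0}})
        sets = db.build_marker_sets(stats, "one_vs_all_top_n", {"n": 2})
        assert sets.sets["A"] == ["g1", "g2"]


class TestDisjointness:
    """A gene can have mean ratio > 1 for at most one cell type."""

    @pytest.mark.parametrize("seed", range(5))
    def test_over2_and_mad3_sets_pairwise_disjoint(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.lognormal(0, 1, size=(5, 120))
        tm = TypeMeans(mat, list("ABCDE"), [f"g{i:03d}" for i in range(120)])
        frames = []
        for ct in tm.cell_type_ids:
            res = db.mean_ratio(tm, ct).reset_index()
            res["cell_type"] = ct
            res["rank_fc"] = res["rank_ratio"]
            res["logFC_1vall"] = res["mean_ratio"]
            frames.append(res)
        stats = pd.concat(frames, ignore_index=True)
        for rule, params in [("mean_ratio_over_t", {"t": 2.0}),
                             ("mean_ratio_mad_k", {"k": 3.0})]:
            sets = db.build_marker_sets(stats, rule, params)
            seen = set()
            for genes in sets.sets.values():
                assert not (seen & set(genes))
                seen |= set(genes)

    def test_gene_exceeds_one_for_at_most_one_type(self):
        rng = np.random.default_rng(77)
        mat = rng.lognormal(0, 1, size=(6, 200))
        tm = TypeMeans(mat, list("ABCDEF"), [f"g{i:03d}" for i in range(200)])
        above = np.zeros(200, dtype=int)
        for ct in tm.cell_type_ids:
            above += (db.mean_ratio(tm, ct)["mean_ratio"] > 1).to_numpy()
        assert np.all(above <= 1)


class TestPlantedMarkerRecovery:
    def test_planted_markers_rank_first_for_their_type(self, small_reference,
                                                       small_markers):
        _, _, truth = small_reference
        recovered = 0
        total = 0
        for ct, genes in small_markers.sets.items():
            planted = set(truth.planted_markers(ct))
            total += len(planted)
            recovered += len(planted & set(genes))
        assert recovered / total >= 0.95
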