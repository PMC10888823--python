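"""Proportion estimators, cell-size adjustment, and type collapsing."""

import itertools

import numpy as np
import pandas as pd
import pytest

import deconvbench as db
from deconvbench.data_model import DataModelError
from deconvbench.deconvolution import ProportionTable, SignatureMatrix
from deconvbench.markers import MarkerSets


def _random_signature(rng, n_genes=40, types=("A", "B", "C", "D", "E")):
    vals = rng.lognormal(0, 1, size=(n_genes, len(types)))
    return SignatureMatrix(vals, [f"g{i:03d}" for i in range(n_genes)],
                           list(types))


def _bulk_from(sig, props, unit_prefix="s"):
    props = np.atleast_2d(props)
    vals = sig.values @ props.T
    return db.ExpressionMatrix(vals, sig.gene_ids,
                               [f"{unit_prefix}{i}" for i in range(props.shape[0])],
                               scale="cpm")


def two_type_grid_oracle(sig2, y, step=1e-4):
    """Exhaustive grid search over 2-type mixtures, independent of NNLS."""
    best_p, best_loss = 0.0, np.inf
    for p in np.arange(0.0, 1.0 + step, step):
        resid = y - sig2 @ np.array([p, 1 - p])
        loss = float(resid @ resid)
        if loss < best_loss:
            best_p, best_loss = p, loss
    return best_p


class TestSignatureFromReference:
    def test_one_marker_per_type(self):
        expr = db.ExpressionMatrix(np.array([[10.0, 0.0], [0.0, 8.0]]),
                                   ["gA", "gB"], ["c1", "c2"], scale="cpm")
        ann = db.CellAnnotation(["c1", "c2"], ["A", "B"])
        markers = MarkerSets({"A": ["gA"], "B": ["gB"]}, rule="loaded")
        sig = db.signature_from_reference(expr, ann, markers)
        frame = sig.to_frame()
        assert frame.loc["gA", "A"] == 10.0
        assert frame.loc["gB", "B"] == 8.0

    def test_all_genes_equals_type_means_restricted(self):
        rng = np.random.default_rng(31)
        expr = db.ExpressionMatrix(rng.random((20, 30)) * 10,
                                   [f"g{i:02d}" for i in range(20)],
                                   [f"c{i}" for i in range(30)], scale="cpm")
        ann = db.CellAnnotation(expr.unit_ids, [f"T{i % 3}" for i in range(30)])
        markers = MarkerSets({"T0": list(expr.gene_ids)}, rule="loaded")
        sig = db.signature_from_reference(expr, ann, markers)
        tm = db.type_means(expr, ann)
        assert np.allclose(sig.to_frame().loc[sorted(expr.gene_ids)].to_numpy(),
                           tm.to_frame().T.loc[sorted(expr.gene_ids)].to_numpy())

    def test_absent_marker_gene_rejected(self):
        expr = db.ExpressionMatrix(np.ones((2, 2)), ["g1", "g2"],
                                   ["c1", "c2"], scale="cpm")
        ann = db.CellAnnotation(["c1", "c2"], ["A", "B"])
        with pytest.raises(DataModelError, match="absent"):
            db.signature_from_reference(expr, ann,
                                        MarkerSets({"A": ["gX"]}, rule="loaded"))


class TestNNLS:
    def test_exact_two_type_mixture_recovered(self):
        rng = np.random.default_rng(32)
        sig = _random_signature(rng, 30, ("A", "B"))
        bulk = _bulk_from(sig, np.array([[0.7, 0.3]]))
        props = db.deconvolve_nnls(bulk, sig)
        assert np.allclose(props.values.to_numpy(), [[0.7, 0.3]], atol=1e-6)

    def test_pure_column_gets_proportion_one(self):
        rng = np.random.default_rng(33)
        sig = _random_signature(rng, 30)
        bulk = _bulk_from(sig, np.eye(5)[2])
        props = db.deconvolve_nnls(bulk, sig)
        assert props.values.to_numpy()[0, 2] == pytest.approx(1.0, abs=1e-6)

    def test_random_noiseless_mixtures_recovered(self):
        rng = np.random.default_rng(34)
        sig = _random_signature(rng, 60)
        truth = rng.dirichlet(np.ones(5), size=50)
        bulk = _bulk_from(sig, truth)
        props = db.deconvolve_nnls(bulk, sig)
        assert np.max(np.abs(props.values.to_numpy() - truth)) < 1e-6

    def test_agrees_with_grid_search_on_two_type_subproblems(self):
        rng = np.random.default_rng(35)
        sig = _random_signature(rng, 25, ("A", "B"))
        for p_true in (0.2, 0.5, 0.9):
            y = sig.values @ np.array([p_true, 1 - p_true])
            bulk = db.ExpressionMatrix(y[:, None], sig.gene_ids, ["s0"],
                                       scale="cpm")
            est = db.deconvolve_nnls(bulk, sig).values.to_numpy()[0, 0]
            grid = two_type_grid_oracle(sig.values, y)
            assert est == pytest.approx(grid, abs=2e-4)

    def test_scale_invariance_of_the_estimate(self):
        rng = np.random.default_rng(36)
        sig = _random_signature(rng, 40)
        truth = rng.dirichlet(np.ones(5), size=3)
        bulk = _bulk_from(sig, truth)
        scaled = db.ExpressionMatrix(bulk.values * 37.5, bulk.gene_ids,
                                     bulk.unit_ids, scale="cpm")
        p1 = db.deconvolve_nnls(bulk, sig).values.to_numpy()
        p2 = db.deconvolve_nnls(scaled, sig).values.to_numpy()
        assert np.allclose(p1, p2, atol=1e-9)

    def test_rank_deficient_signature_rejected(self):
        vals = np.ones((10, 2))
        sig = SignatureMatrix(vals, [f"g{i}" for i in range(10)], ["A", "B"])
        bulk = db.ExpressionMatrix(np.ones((10, 1)), sig.gene_ids, ["s"],
                                   scale="cpm")
        with pytest.raises(DataModelError, match="rank"):
            db.deconvolve_nnls(bulk, sig)

    def test_all_zero_bulk_falls_back_to_uniform_with_warning(self):
        rng = np.random.default_rng(37)
        sig = _random_signature(rng, 20, ("A", "B", "C"))
        bulk = db.ExpressionMatrix(np.zeros((20, 1)), sig.gene_ids, ["s"],
                                   scale="cpm")
        props = db.deconvolve_nnls(bulk, sig)
        assert np.allclose(props.values.to_numpy(), 1 / 3)
        assert props.warnings


class TestMarkerRatio:
    def _specific_setup(self, rng, n_per_type=3, types=("A", "B", "C")):
        """Signature with perfectly specific markers (zero off-target)."""
        n_genes = n_per_type * len(types)
        genes = [f"g{i:02d}" for i in range(n_genes)]
        vals = np.zeros((n_genes, len(types)))
        sets = {}
        for k, ct in enumerate(types):
            rows = range(k * n_per_type, (k + 1) * n_per_type)
            for r in rows:
                vals[r, k] = rng.uniform(1, 10)
            sets[ct] = [genes[r] for r in rows]
        sig = SignatureMatrix(vals, genes, list(types))
        return sig, MarkerSets(sets, rule="loaded")

    def test_pure_bulk_gives_proportion_one(self):
        rng = np.random.default_rng(38)
        sig, markers = self._specific_setup(rng)
        bulk = _bulk_from(sig, np.eye(3)[0])
        props = db.deconvolve_marker_ratio(bulk, sig, markers)
        assert props.values.to_numpy()[0, 0] == pytest.approx(1.0)

    def test_symmetric_scores_give_half_half(self):
        sig = SignatureMatrix(np.array([[2.0, 0.0], [0.0, 2.0]]),
                              ["gA", "gB"], ["A", "B"])
        markers = MarkerSets({"A": ["gA"], "B": ["gB"]}, rule="loaded")
        bulk = db.ExpressionMatrix(np.array([[4.0], [4.0]]), ["gA", "gB"],
                                   ["s"], scale="cpm")
        props = db.deconvolve_marker_ratio(bulk, sig, markers)
        assert np.allclose(props.values.to_numpy(), [[0.5, 0.5]])

    def test_specific_markers_recover_rna_fractions(self):
        rng = np.random.default_rng(39)
        sig, markers = self._specific_setup(rng, n_per_type=4,
                                            types=("A", "B", "C", "D"))
        truth = rng.dirichlet(np.ones(4), size=10)
        bulk = _bulk_from(sig, truth)
        props = db.deconvolve_marker_ratio(bulk, sig, markers)
        assert np.allclose(props.values.to_numpy(), truth, atol=1e-8)

    def test_empty_marker_set_rejected(self):
        sig = SignatureMatrix(np.ones((2, 2)) + np.eye(2), ["g1", "g2"],
                              ["A", "B"])
        bulk = db.ExpressionMatrix(np.ones((2, 1)), sig.gene_ids, ["s"],
                                   scale="cpm")
        with pytest.raises(DataModelError, match="empty marker set"):
            db.deconvolve_marker_ratio(bulk, sig,
                                       MarkerSets({"A": ["g1"], "B": []},
                                                  rule="loaded"))


class TestCellSizeAdjust:
    def _table(self, vals, types):
        frame = pd.DataFrame(np.atleast_2d(vals),
                             index=[f"s{i}" for i in range(np.atleast_2d(vals).shape[0])],
                             columns=types)
        return ProportionTable(frame)

    def test_equal_sizes_are_identity(self):
        rng = np.random.default_rng(41)
        table = self._table(rng.dirichlet(np.ones(4), size=6), list("ABCD"))
        out = db.cell_size_adjust(table, {ct: 2.5 for ct in "ABCD"})
        assert np.allclose(out.values.to_numpy(), table.values.to_numpy())

    def test_known_arithmetic(self):
        table = self._table([0.5, 0.5], ["A", "B"])
        out = db.cell_size_adjust(table, {"A": 2.0, "B": 1.0})
        assert np.allclose(out.values.to_numpy(), [[1 / 3, 2 / 3]])

    def test_inverts_rna_fraction_construction(self):
        rng = np.random.default_rng(42)
        types = list("ABCDE")
        sizes = dict(zip(types, rng.uniform(0.5, 3.0, size=5)))
        cell_fracs = rng.dirichlet(np.ones(5), size=20)
        rna = cell_fracs * np.array([sizes[t] for t in types])
        rna = rna / rna.sum(axis=1, keepdims=True)
        out = db.cell_size_adjust(self._table(rna, types), sizes)
        assert np.allclose(out.values.to_numpy(), cell_fracs, atol=1e-10)

    def test_missing_or_nonpositive_size_rejected(self):
        table = self._table([0.5, 0.5], ["A", "B"])
        with pytest.raises(DataModelError):
            db.cell_size_adjust(table, {"A": 1.0})
        with pytest.raises(DataModelError):
            db.cell_size_adjust(table, {"A": 1.0, "B": 0.0})


class TestCollapseCellTypes:
    def test_oligo_opc_sum(self):
        frame = pd.DataFrame([[0.10, 0.02, 0.88]], index=["s"],
                             columns=["Oligo", "OPC", "Excit"])
        out = db.collapse_cell_types(ProportionTable(frame),
                                     {"Oligo": "OligoOPC", "OPC": "OligoOPC"})
        assert out.values.loc["s", "OligoOPC"] == pytest.approx(0.12)

    def test_identity_mapping_unchanged(self):
        rng = np.random.default_rng(43)
        frame = pd.DataFrame(rng.dirichlet(np.ones(3), size=4),
                             index=[f"s{i}" for i in range(4)],
                             columns=["A", "B", "C"])
        out = db.collapse_cell_types(ProportionTable(frame),
                                     {"A": "A", "B": "B"})
        assert np.allclose(out.values[["A", "B", "C"]].to_numpy(),
                           frame.to_numpy())

    def test_rows_still_sum_to_one_under_arbitrary_partition(self):
        rng = np.random.default_rng(44)
        types = [f"T{i}" for i in range(6)]
        frame = pd.DataFrame(rng.dirichlet(np.ones(6), size=10),
                             index=[f"s{i}" for i in range(10)], columns=types)
        mapping = {"T0": "M1", "T1": "M1", "T2": "M2", "T3": "M2",
                   "T4": "M3", "T5": "M3"}
        out = db.collapse_cell_types(ProportionTable(frame), mapping)
        assert np.allclose(out.values.sum(axis=1), 1.0)

    def test_collision_with_existing_column_rejected(self):
        frame = pd.DataFrame([[0.5, 0.3, 0.2]], index=["s"],
                             columns=["A", "B", "C"])
        with pytest.raises(DataModelError, match="collides"):
            db.collapse_cell_types(ProportionTable(frame), {"A": "B"})
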