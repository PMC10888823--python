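"""Baseline reference-based proportion estimators and proportion transforms.

Two in-repo estimators are provided, both operating on linear (CPM) scale:

* :func:`deconvolve_nnls` — per-sample non-negative least squares against a
  signature matrix of per-type mean reference expression, renormalised to
  proportions.
* :func:`deconvolve_marker_ratio` — per type, the mean over that type's
  marker genes of bulk expression divided by the type's signature value; a
  simple ratio estimator in the spirit of marker-averaging methods.

External methods plug in through :func:`register_estimator`: any callable
``f(bulk, signature, markers) -> ProportionTable`` can be benchmarked by the
harness without the toolkit knowing its internals.

Because cell types differ in RNA content, estimators that match RNA
abundance recover *RNA fractions*; :func:`cell_size_adjust` divides by
per-type size factors and renormalises to convert those into cell-count
proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls

from .data_model import CellAnnotation, DataModelError, ExpressionMatrix
from .markers import MarkerSets, TypeMeans, type_means

logger = logging.getLogger(__name__)


@dataclass
class SignatureMatrix:
    """gene x cell-type matrix of linear-scale reference mean expression."""

    values: np.ndarray
    gene_ids: list[str]
    cell_type_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_type_ids)):
            raise DataModelError("SignatureMatrix shape mismatch")
        if np.any(self.values < 0):
            raise DataModelError("SignatureMatrix must be non-negative")

    @property
    def full_rank(self) -> bool:
        return np.linalg.matrix_rank(self.values) == len(self.cell_type_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.cell_type_ids)


@dataclass
class ProportionTable:
    """unit x cell-type proportions summing to 1 per row, plus metadata."""

    values: pd.DataFrame  # units x cell types
    method: str = ""
    marker_set: str = ""
    strata: pd.DataFrame | None = None  # per-unit metadata, same index
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if np.any(vals < -1e-12):
            raise DataModelError("negative proportions")
        sums = vals.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise DataModelError("proportion rows must sum to 1")
        if self.strata is not None and not self.strata.index.equals(self.values.index):
            raise DataModelError("strata index does not match proportion units")

    @property
    def unit_ids(self) -> list[str]:
        return [str(u) for u in self.values.index]

    @property
    def cell_types(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    def write(self, path, sep: str = "\t") -> None:
        out = self.values.copy()
        if self.strata is not None:
            out = out.join(self.strata)
        out.insert(0, "method", self.method)
        out.insert(1, "marker_set", self.marker_set)
        out.to_csv(path, sep=sep, index_label="unit")


def signature_from_reference(ref_cpm: ExpressionMatrix,
                             annotation: CellAnnotation,
                             markers: MarkerSets) -> SignatureMatrix:
    """Per-type mean CPM over the union of marker genes, genes sorted."""
    genes = sorted(markers.all_genes())
    if not genes:
        raise DataModelError("marker sets are empty")
    missing = [g for g in genes if g not in set(ref_cpm.gene_ids)]
    if missing:
        raise DataModelError(f"marker genes absent from reference: {missing[:5]}")
    means = type_means(ref_cpm.subset_genes(genes), annotation)
    return SignatureMatrix(means.values.T, genes, means.cell_type_ids)


def _align_bulk(bulk: ExpressionMatrix, sig: SignatureMatrix) -> np.ndarray:
    missing = [g for g in sig.gene_ids if g not in set(bulk.gene_ids)]
    if missing:
        raise DataModelError(f"signature genes absent from bulk: {missing[:5]}")
    return bulk.subset_genes(sig.gene_ids).values


def deconvolve_nnls(bulk: ExpressionMatrix, sig: SignatureMatrix,
                    markers: MarkerSets | None = None,
                    method_tag: str = "nnls") -> ProportionTable:
    """Non-negative least squares estimate of per-sample type proportions.

    Solves ``min ||y - S w||_2, w >= 0`` for each bulk column and returns
    ``p = w / sum(w)``.  All-zero solutions fall back to uniform proportions
    with a warning record.  The estimate is invariant to rescaling of the
    bulk column.
    """
    if not sig.full_rank:
        raise DataModelError("signature matrix is rank deficient")
    y = _align_bulk(bulk, sig)
    n_types = len(sig.cell_type_ids)
    props = np.empty((bulk.n_units, n_types))
    warnings: list[str] = []
    for j in range(bulk.n_units):
        w, _ = _scipy_nnls(sig.values, y[:, j])
        total = w.sum()
        if total == 0:
            warnings.append(f"{bulk.unit_ids[j]}: all-zero NNLS solution; "
                            "uniform fallback")
            props[j] = 1.0 / n_types
        else:
            props[j] = w / total
    frame = pd.DataFrame(props, index=bulk.unit_ids, columns=sig.cell_type_ids)
    return ProportionTable(frame, method=method_tag, warnings=warnings)


def deconvolve_marker_ratio(bulk: ExpressionMatrix, sig: SignatureMatrix,
                            markers: MarkerSets,
                            method_tag: str = "marker_ratio") -> ProportionTable:
    """Marker-averaged ratio estimator.

    For each type k the score is the mean over its markers g of
    ``bulk_g / sig_{g,k}`` (terms with a zero signature entry are skipped);
    scores are renormalised to proportions.  With perfectly specific markers
    this recovers the RNA-fraction composition exactly.
    """
    for ct in sig.cell_type_ids:
        if not markers.sets.get(ct):
            raise DataModelError(f"empty marker set for cell type {ct!r}")
    gene_index = {g: i for i, g in enumerate(sig.gene_ids)}
    bulk_vals = _align_bulk(bulk, sig)  # sig genes x units
    scores = np.zeros((bulk.n_units, len(sig.cell_type_ids)))
    for k, ct in enumerate(sig.cell_type_ids):
        rows = np.array([gene_index[g] for g in markers.sets[ct]
                         if g in gene_index], dtype=int)
        if rows.size == 0:
            raise DataModelError(f"no usable marker genes for {ct!r}")
        sig_col = sig.values[rows, k]
        usable = sig_col > 0  # zero-signature terms are skipped
        if usable.any():
            ratios = bulk_vals[rows[usable], :] / sig_col[usable, None]
            scores[:, k] = ratios.mean(axis=0)
    totals = scores.sum(axis=1)
    warnings = [f"{bulk.unit_ids[j]}: all-zero marker scores; uniform fallback"
                for j in np.flatnonzero(totals == 0)]
    safe = np.where(totals > 0, totals, 1.0)[:, None]
    props = np.where(totals[:, None] > 0, scores / safe,
                     1.0 / len(sig.cell_type_ids))
    frame = pd.DataFrame(props, index=bulk.unit_ids, columns=sig.cell_type_ids)
    return ProportionTable(frame, method=method_tag, warnings=warnings)


# ---------------------------------------------------------------------------
# Estimator registry (plug-in contract for external methods)
# ---------------------------------------------------------------------------

Estimator = Callable[[ExpressionMatrix, SignatureMatrix, MarkerSets],
                     ProportionTable]

_ESTIMATORS: dict[str, Estimator] = {}


def register_estimator(name: str, fn: Estimator) -> None:
    """Register a deconvolution method under ``name`` for harness use."""
    _ESTIMATORS[name] = fn


def get_estimator(name: str) -> Estimator:
    if name not in _ESTIMATORS:
        raise DataModelError(
            f"unknown estimator {name!r}; registered: {sorted(_ESTIMATORS)}")
    return _ESTIMATORS[name]


def list_estimators() -> list[str]:
    return sorted(_ESTIMATORS)


register_estimator("nnls", deconvolve_nnls)
register_estimator("marker_ratio", deconvolve_marker_ratio)


# ---------------------------------------------------------------------------
# Proportion transforms
# ---------------------------------------------------------------------------

def cell_size_adjust(props: ProportionTable,
                     sizes: Mapping[str, float]) -> ProportionTable:
    """Convert RNA-fraction proportions to cell-count proportions.

    ``q_k \\propto p_k / s_k`` renormalised per unit, where ``s_k`` is the
    per-type size (RNA content) factor.  Equal sizes leave the table fixed.
    """
    for ct in props.cell_types:
        if ct not in sizes:
            raise DataModelError(f"missing size factor for {ct!r}")
        if not np.isfinite(sizes[ct]) or sizes[ct] <= 0:
            raise DataModelError(f"size factor for {ct!r} must be positive")
    s = np.array([sizes[ct] for ct in props.cell_types], dtype=float)
    vals = props.values.to_numpy(dtype=float) / s
    sums = vals.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    frame = pd.DataFrame(vals / sums, index=props.values.index,
                         columns=props.values.columns)
    return ProportionTable(frame, method=props.method + "+size_adj",
                           marker_set=props.marker_set, strata=props.strata)


def collapse_cell_types(props: ProportionTable,
                        mapping: Mapping[str, str]) -> ProportionTable:
    """Merge source cell types into combined columns by summation.

    ``mapping`` sends each source type to its merged name (e.g. Oligo and
    OPC both to OligoOPC, matching an imaging panel that cannot separate
    them).  Types not mentioned keep their own name.  A merged name may not
    collide with an unmerged existing column.
    """
    present = set(props.cell_types)
    for src in mapping:
        if src not in present:
            raise DataModelError(f"mapping source {src!r} not in table")
    full = {ct: mapping.get(ct, ct) for ct in props.cell_types}
    for src, dst in mapping.items():
        # a merged name may reuse an existing column only if that column is
        # itself part of the merge group
        if dst != src and dst in present and dst not in mapping:
            raise DataModelError(
                f"merged name {dst!r} collides with existing column")
    out: dict[str, np.ndarray] = {}
    for ct in props.cell_types:
        dst = full[ct]
        col = props.values[ct].to_numpy(dtype=float)
        out[dst] = out.get(dst, 0) + col
    frame = pd.DataFrame(out, index=props.values.index)
    return ProportionTable(frame, method=props.method,
                           marker_set=props.marker_set, strata=props.strata)
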