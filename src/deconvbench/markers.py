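"""Cell-type marker gene selection for deconvolution.

Two ranking statistics are implemented:

* **Mean Ratio** — for a target cell type, the ratio of a gene's mean
  expression in the target type over the *highest* mean among the non-target
  types.  Values above 1 indicate target-specific expression; the statistic
  penalises genes that are merely high everywhere, which a one-vs-all fold
  change does not.
* **1vALL** — a Welch two-sample t-test of the target type against all other
  cells pooled into one group, ranked by log fold change.

From these, named marker-gene sets are built: the full common-gene set,
top-N by either ranking, all genes with Mean Ratio above a fixed threshold,
and a per-type adaptive threshold at k MADs above the median of ratios > 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (MAD_CONSTANT, CellAnnotation, DataModelError,
                         ExpressionMatrix)

MARKER_RULES = ("full", "one_vs_all_top_n", "mean_ratio_top_n",
                "mean_ratio_over_t", "mean_ratio_mad_k")


@dataclass
class TypeMeans:
    """cell-type x gene matrix of mean expression on a linear scale."""

    values: np.ndarray  # n_types x n_genes
    cell_type_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_type_ids), len(self.gene_ids)):
            raise DataModelError("TypeMeans shape mismatch")
        if np.any(self.values < 0):
            raise DataModelError("TypeMeans must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_type_ids,
                            columns=self.gene_ids)


@dataclass
class MarkerSets:
    """Named per-cell-type marker gene lists plus the rule that built them."""

    sets: dict[str, list[str]]
    rule: str
    params: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ct, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise DataModelError(f"duplicate genes in marker set for {ct}")

    def all_genes(self) -> list[str]:
        """Union of all marker genes, deduplicated, in set order."""
        seen: dict[str, None] = {}
        for genes in self.sets.values():
            for g in genes:
                seen.setdefault(g, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = [(ct, g) for ct, genes in self.sets.items() for g in genes]
        return pd.DataFrame(rows, columns=["cell_type", "gene"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def type_means(expr: ExpressionMatrix, annotation: CellAnnotation) -> TypeMeans:
    """Arithmetic mean expression of each gene within each cell type.

    Expects linear-scale (cpm) expression; means over log values would change
    the statistic being computed downstream.
    """
    if expr.scale not in ("cpm", "counts"):
        raise DataModelError("type_means expects linear-scale expression")
    if set(expr.unit_ids) != set(annotation.unit_ids):
        raise DataModelError("annotation units do not match expression units")
    per_unit = dict(zip(annotation.unit_ids, annotation.cell_type))
    labels = np.array([per_unit[u] for u in expr.unit_ids])
    types = annotation.types()
    means = np.empty((len(types), expr.n_genes))
    for i, ct in enumerate(types):
        mask = labels == ct
        if not mask.any():
            raise DataModelError(f"cell type {ct!r} has no cells")
        means[i] = expr.values[:, mask].mean(axis=1)
    return TypeMeans(means, types, list(expr.gene_ids))


def mean_ratio(means: TypeMeans, target: str) -> pd.DataFrame:
    """Mean Ratio statistic of every gene for one target cell type.

    ratio = mean(target) / max over non-target type means.  When the
    non-target maximum is zero the ratio is ``+inf`` if the target mean is
    positive and 0 if it is zero.  ``rank_ratio`` orders genes by descending
    ratio, breaking ties by descending target mean then ascending gene id.

    Returns a DataFrame indexed by gene with columns
    ``mean_ratio``, ``second_type``, ``target_mean``, ``rank_ratio``.
    """
    if target not in means.cell_type_ids:
        raise DataModelError(f"unknown target cell type {target!r}")
    if len(means.cell_type_ids) < 2:
        raise DataModelError("mean_ratio requires at least two cell types")
    ti = means.cell_type_ids.index(target)
    other_idx = [i for i in range(len(means.cell_type_ids)) if i != ti]
    other = means.values[other_idx, :]
    target_mean = means.values[ti, :]
    # argmax gives the first (lowest-index) maximiser -> deterministic ties
    arg = np.argmax(other, axis=0)
    denom = other[arg, np.arange(other.shape[1])]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, target_mean / np.where(denom > 0, denom, 1.0),
                         np.where(target_mean > 0, np.inf, 0.0))
    second = [means.cell_type_ids[other_idx[a]] for a in arg]
    frame = pd.DataFrame({
        "mean_ratio": ratio,
        "second_type": second,
        "target_mean": target_mean,
    }, index=pd.Index(means.gene_ids, name="gene"))
    # sort keys: descending ratio (inf first), descending target mean, gene id
    keyed = sorted(range(len(means.gene_ids)),
                   key=lambda i: (-ratio[i], -target_mean[i], means.gene_ids[i]))
    rank = np.empty(len(means.gene_ids), dtype=int)
    for r, i in enumerate(keyed, start=1):
        rank[i] = r
    frame["rank_ratio"] = rank
    return frame


def one_vs_all(expr: ExpressionMatrix, annotation: CellAnnotation,
               target: str) -> pd.DataFrame:
    """Welch t-test of the target type against all other cells pooled.

    Expects log-scale expression.  Returns a DataFrame indexed by gene with
    ``logFC_1vall`` (mean difference on the log scale), ``t_stat``,
    ``p_value``, ``rank_fc`` and a ``degenerate`` flag for genes where both
    groups have zero variance.  Convention for zero-variance genes: equal
    means give t = 0, p = 1; unequal means give t = +/-inf, p = 0 with the
    flag set.
    """
    if expr.scale != "log":
        raise DataModelError("one_vs_all expects log-scale expression")
    if target not in annotation.types():
        raise DataModelError(f"unknown target cell type {target!r}")
    per_unit = dict(zip(annotation.unit_ids, annotation.cell_type))
    labels = np.array([per_unit[u] for u in expr.unit_ids])
    in_target = labels == target
    n1, n2 = int(in_target.sum()), int((~in_target).sum())
    if n1 < 2:
        raise DataModelError(f"target group {target!r} has fewer than 2 cells")
    if n2 < 2:
        raise DataModelError("rest group has fewer than 2 cells")
    x = expr.values[:, in_target]
    y = expr.values[:, ~in_target]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1, v2 = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    logfc = m1 - m2
    se2 = v1 / n1 + v2 / n2
    t = np.zeros_like(logfc)
    p = np.ones_like(logfc)
    degenerate = se2 == 0
    ok = ~degenerate
    t[ok] = logfc[ok] / np.sqrt(se2[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2[ok] ** 2 / ((v1[ok] / n1) ** 2 / (n1 - 1)
                             + (v2[ok] / n2) ** 2 / (n2 - 1))
    p[ok] = 2 * stats.t.sf(np.abs(t[ok]), df)
    # zero variance in both groups: equal means -> t=0,p=1; else infinite t
    diff = degenerate & (logfc != 0)
    t[diff] = np.sign(logfc[diff]) * np.inf
    p[diff] = 0.0
    frame = pd.DataFrame({
        "logFC_1vall": logfc,
        "t_stat": t,
        "p_value": p,
        "degenerate": degenerate,
    }, index=pd.Index(expr.gene_ids, name="gene"))
    keyed = sorted(range(expr.n_genes),
                   key=lambda i: (-logfc[i], p[i], expr.gene_ids[i]))
    rank = np.empty(expr.n_genes, dtype=int)
    for r, i in enumerate(keyed, start=1):
        rank[i] = r
    frame["rank_fc"] = rank
    return frame


def marker_stats(expr_cpm: ExpressionMatrix, expr_log: ExpressionMatrix,
                 annotation: CellAnnotation) -> pd.DataFrame:
    """Long-format per-(gene, cell type) marker statistics for all types."""
    means = type_means(expr_cpm, annotation)
    frames = []
    for ct in means.cell_type_ids:
        mr = mean_ratio(means, ct)
        ova = one_vs_all(expr_log, annotation, ct)
        merged = mr.join(ova)
        merged.insert(0, "cell_type", ct)
        frames.append(merged.reset_index())
    return pd.concat(frames, ignore_index=True)


def build_marker_sets(stats_table: pd.DataFrame, rule: str,
                      params: Mapping | None = None,
                      common_genes: Iterable[str] | None = None) -> MarkerSets:
    """Construct named marker sets from long-format marker statistics.

    Rules
    -----
    ``full``
        every common gene, for every cell type.
    ``one_vs_all_top_n`` / ``mean_ratio_top_n``
        the N best-ranked genes per type (by ``rank_fc`` / ``rank_ratio``),
        *then* intersected with ``common_genes`` — sets may end up smaller
        than N.
    ``mean_ratio_over_t``
        all genes with mean_ratio > t, then intersected.
    ``mean_ratio_mad_k``
        per type, all genes with mean_ratio strictly above
        ``median(R) + k * MAD(R)`` where R are that type's ratios > 1
        (MAD scaled by 1.4826).  An empty R yields an empty set with a
        warning record rather than an error.
    """
    if rule not in MARKER_RULES:
        raise DataModelError(f"unknown marker rule {rule!r}")
    params = dict(params or {})
    cell_types = list(dict.fromkeys(stats_table["cell_type"]))
    all_genes = list(dict.fromkeys(stats_table["gene"]))
    common = set(common_genes) if common_genes is not None else set(all_genes)
    sets: dict[str, list[str]] = {}
    warnings: list[str] = []
    for ct in cell_types:
        sub = stats_table[stats_table["cell_type"] == ct]
        if rule == "full":
            genes = [g for g in all_genes if g in common]
        elif rule == "one_vs_all_top_n":
            n = int(params.get("n", 25))
            ranked = sub.sort_values("rank_fc")
            genes = [g for g in ranked["gene"].head(n) if g in common]
        elif rule == "mean_ratio_top_n":
            n = int(params.get("n", 25))
            ranked = sub.sort_values("rank_ratio")
            genes = [g for g in ranked["gene"].head(n) if g in common]
        elif rule == "mean_ratio_over_t":
            t = float(params.get("t", 2.0))
            ranked = sub.sort_values("rank_ratio")
            genes = [g for g, r in zip(ranked["gene"], ranked["mean_ratio"])
                     if r > t and g in common]
        else:  # mean_ratio_mad_k
            k = float(params.get("k", 3.0))
            ratios = sub["mean_ratio"].to_numpy(dtype=float)
            pool = ratios[ratios > 1]
            if pool.size == 0:
                warnings.append(f"{ct}: no mean ratios > 1; empty marker set")
                sets[ct] = []
                continue
            med = float(np.median(pool))
            mad = MAD_CONSTANT * float(np.median(np.abs(pool - med)))
            thresh = med + k * mad
            ranked = sub.sort_values("rank_ratio")
            genes = [g for g, r in zip(ranked["gene"], ranked["mean_ratio"])
                     if r > thresh and g in common]
        sets[ct] = genes
    return MarkerSets(sets, rule, params, warnings)
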