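"""Accuracy and consistency metrics for deconvolution benchmarking.

Predicted proportions are scored against orthogonal truth (e.g. imaging-
derived section proportions) with Pearson correlation, root mean squared
error, and relative rmse (rmse divided by the mean of the truth values in
the evaluated scope).  Metrics pool all (unit, cell type) pairs within a
scope; scopes can be overall, per stratum, or per cell type.

Also here: pairwise method agreement, within-block consistency of the
neuronal fraction (relative standard deviation), one-sided Fisher exact
enrichment of marker sets in arbitrary gene sets, and Benjamini-Hochberg
FDR adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import DataModelError
from .deconvolution import ProportionTable


@dataclass
class EvalResult:
    """Pooled accuracy metrics for one evaluation scope."""

    scope: str
    cor: float | None       # None when undefined (zero variance / <2 pairs)
    rmse: float
    rrmse: float | None     # None when mean truth is 0
    n_pairs: int
    cor_undefined_reason: str | None = None


def _pooled_metrics(pred: np.ndarray, truth: np.ndarray, scope: str) -> EvalResult:
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    n = pred.size
    rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
    mean_truth = float(np.mean(truth))
    rrmse = rmse / mean_truth if mean_truth > 0 else None
    cor: float | None
    reason = None
    if n < 2:
        cor, reason = None, "fewer than 2 pairs"
    elif np.std(pred) == 0 or np.std(truth) == 0:
        cor, reason = None, "zero variance"
    else:
        cor = float(np.corrcoef(pred, truth)[0, 1])
    return EvalResult(scope, cor, rmse, rrmse, n, reason)


def compare_proportions(pred: ProportionTable, truth: ProportionTable,
                        group_by: str | None = None,
                        per_cell_type: bool = False) -> list[EvalResult]:
    """Score predictions against truth over matched units and shared types.

    Units are matched on their ids; cell-type columns must agree after any
    collapsing has been applied upstream.  Metrics are pooled over all
    (unit, cell type) pairs in each scope.  ``group_by`` names a column of
    the prediction table's strata metadata to evaluate per stratum;
    ``per_cell_type`` instead scopes by cell type.
    """
    common_units = [u for u in pred.unit_ids if u in set(truth.unit_ids)]
    if not common_units:
        raise DataModelError("no matched units between prediction and truth")
    shared = [c for c in pred.cell_types if c in set(truth.cell_types)]
    if not shared:
        raise DataModelError("no shared cell types after collapsing")
    p = pred.values.loc[common_units, shared]
    t = truth.values.loc[common_units, shared]
    results: list[EvalResult] = []
    if group_by is None and not per_cell_type:
        return [_pooled_metrics(p.to_numpy(), t.to_numpy(), "overall")]
    if per_cell_type:
        for ct in shared:
            results.append(_pooled_metrics(p[ct].to_numpy(), t[ct].to_numpy(),
                                           f"cell_type={ct}"))
        return results
    if pred.strata is None or group_by not in pred.strata.columns:
        raise DataModelError(f"stratum column {group_by!r} not in prediction strata")
    labels = pred.strata.loc[common_units, group_by]
    for val in dict.fromkeys(labels):
        units = [u for u, lab in zip(common_units, labels) if lab == val]
        results.append(_pooled_metrics(p.loc[units].to_numpy(),
                                       t.loc[units].to_numpy(),
                                       f"{group_by}={val}"))
    return results


def method_correlation_matrix(tables: Sequence[ProportionTable]) -> pd.DataFrame:
    """Pairwise Pearson correlation of methods' pooled proportion vectors."""
    if not tables:
        raise DataModelError("no tables supplied")
    base_units, base_types = tables[0].unit_ids, tables[0].cell_types
    vectors, names = [], []
    for i, tab in enumerate(tables):
        if set(tab.unit_ids) != set(base_units) or set(tab.cell_types) != set(base_types):
            raise DataModelError("tables do not share units and cell types")
        vectors.append(tab.values.loc[base_units, base_types].to_numpy().ravel())
        names.append(tab.method or f"method_{i}")
    mat = np.corrcoef(np.vstack(vectors))
    mat = np.atleast_2d(mat)
    return pd.DataFrame(mat, index=names, columns=names)


def neuronal_rsd(props: ProportionTable, neuron_types: Iterable[str],
                 block_key: str = "block_id") -> pd.Series:
    """Per-block relative standard deviation of the summed neuronal fraction.

    RSD (coefficient of variation) = sample sd / mean of the neuronal
    fraction across a block's samples.  Blocks with a single sample are
    skipped; a zero mean yields NaN.
    """
    neuron_types = list(neuron_types)
    missing = [c for c in neuron_types if c not in props.cell_types]
    if missing:
        raise DataModelError(f"neuron types not in table: {missing}")
    if props.strata is None or block_key not in props.strata.columns:
        raise DataModelError(f"block column {block_key!r} not in strata")
    frac = props.values[neuron_types].sum(axis=1)
    out: dict[str, float] = {}
    for block, idx in frac.groupby(props.strata[block_key]).groups.items():
        vals = frac.loc[idx].to_numpy(dtype=float)
        if vals.size < 2:
            continue  # skipped with warning semantics: not enough replicates
        mu = vals.mean()
        out[str(block)] = float(vals.std(ddof=1) / mu) if mu > 0 else math.nan
    return pd.Series(out, name="neuronal_rsd")


def fisher_enrichment(marker_set: Iterable[str], target_set: Iterable[str],
                      universe: Iterable[str]) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test of two gene sets.

    Builds the 2x2 table a = |marker & target|, b = |marker - target|,
    c = |target - marker|, d = rest of the universe, and returns the sample
    odds ratio (ad/bc, +inf when bc = 0 and a*d > 0) with the hypergeometric
    upper-tail p-value.
    """
    universe = set(universe)
    if not universe:
        raise DataModelError("empty gene universe")
    marker = set(marker_set) & universe
    target = set(target_set) & universe
    a = len(marker & target)
    b = len(marker - target)
    c = len(target - marker)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    odds, p = stats.fisher_exact(table, alternative="greater")
    return float(odds), float(p)


def enrichment_table(marker_sets: Mapping[str, Iterable[str]],
                     target_sets: Mapping[str, Iterable[str]],
                     universe: Iterable[str]) -> pd.DataFrame:
    """All-pairs marker x target enrichment with BH-adjusted p-values."""
    universe = set(universe)
    rows = []
    for m_name, m_genes in marker_sets.items():
        for t_name, t_genes in target_sets.items():
            odds, p = fisher_enrichment(m_genes, t_genes, universe)
            rows.append((m_name, t_name, odds, p))
    frame = pd.DataFrame(rows, columns=["marker_set", "target_set",
                                        "odds_ratio", "p_value"])
    frame["fdr"] = bh_adjust(frame["p_value"].to_numpy())
    return frame


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DataModelError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
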