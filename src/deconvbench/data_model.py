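"""Core containers and shared preprocessing for deconvolution benchmarking.

The toolkit moves expression data around as :class:`ExpressionMatrix`, a thin
gene x unit wrapper around a dense numpy array with an explicit scale tag
(``counts``, ``cpm`` or ``log``).  Units are either cells/nuclei (reference
side) or bulk samples.  Keeping the scale explicit lets downstream operations
assert their preconditions instead of silently mixing normalisations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

SCALES = ("counts", "cpm", "log")

#: consistency constant making the MAD an unbiased sigma estimate for normals
MAD_CONSTANT = 1.4826


class DataModelError(ValueError):
    """Raised on contract violations in container construction or I/O."""


@dataclass
class ExpressionMatrix:
    """Gene x unit expression matrix with an explicit scale tag.

    Parameters
    ----------
    values
        Non-negative (for counts/cpm) 2-D array, genes in rows, units in
        columns.
    gene_ids, unit_ids
        Unique ordered identifiers matching the matrix dimensions.
    scale
        One of ``counts``, ``cpm``, ``log``.
    """

    values: np.ndarray
    gene_ids: list[str]
    unit_ids: list[str]
    scale: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.unit_ids = [str(u) for u in self.unit_ids]
        if self.values.ndim != 2:
            raise DataModelError("expression values must be 2-D")
        if self.scale not in SCALES:
            raise DataModelError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if len(self.gene_ids) != self.values.shape[0]:
            raise DataModelError(
                f"gene annotation length {len(self.gene_ids)} does not match "
                f"matrix rows {self.values.shape[0]}"
            )
        if len(self.unit_ids) != self.values.shape[1]:
            raise DataModelError(
                f"unit annotation length {len(self.unit_ids)} does not match "
                f"matrix columns {self.values.shape[1]}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataModelError("duplicate gene ids")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise DataModelError("duplicate unit ids")
        if self.scale in ("counts", "cpm") and np.any(self.values < 0):
            raise DataModelError("negative entries in a counts/cpm matrix")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.unit_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``genes`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise DataModelError(f"genes absent from matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(self.values[rows, :].copy(), list(genes),
                                list(self.unit_ids), self.scale)

    def subset_units(self, units: Sequence[str]) -> "ExpressionMatrix":
        index = {u: i for i, u in enumerate(self.unit_ids)}
        missing = [u for u in units if u not in index]
        if missing:
            raise DataModelError(f"units absent from matrix: {missing[:5]}")
        cols = [index[u] for u in units]
        return ExpressionMatrix(self.values[:, cols].copy(), list(self.gene_ids),
                                list(units), self.scale)


@dataclass
class CellAnnotation:
    """Per-cell labels aligned to a reference :class:`ExpressionMatrix`."""

    unit_ids: list[str]
    cell_type: list[str]
    donor_id: list[str] | None = None
    sample_id: list[str] | None = None

    def __post_init__(self) -> None:
        self.unit_ids = [str(u) for u in self.unit_ids]
        self.cell_type = [str(c) for c in self.cell_type]
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise DataModelError("duplicate unit ids in annotation")
        if len(self.cell_type) != len(self.unit_ids):
            raise DataModelError("cell_type length does not match unit_ids")
        if any(c in ("", "nan", "None") for c in self.cell_type):
            raise DataModelError("missing cell_type labels")
        for attr in ("donor_id", "sample_id"):
            val = getattr(self, attr)
            if val is not None and len(val) != len(self.unit_ids):
                raise DataModelError(f"{attr} length does not match unit_ids")

    def to_frame(self) -> pd.DataFrame:
        data = {"cell_type": self.cell_type}
        if self.donor_id is not None:
            data["donor_id"] = self.donor_id
        if self.sample_id is not None:
            data["sample_id"] = self.sample_id
        return pd.DataFrame(data, index=self.unit_ids)

    def types(self) -> list[str]:
        """Distinct cell types in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.cell_type:
            seen.setdefault(c, None)
        return list(seen)

    def field(self, name: str) -> list[str]:
        if name == "cell_type":
            return self.cell_type
        if name == "donor_id" and self.donor_id is not None:
            return self.donor_id
        if name == "sample_id" and self.sample_id is not None:
            return self.sample_id
        raise DataModelError(f"unknown or unset annotation field {name!r}")


LIBRARY_TYPES = ("polyA", "RiboZeroGold")
RNA_EXTRACTIONS = ("Cyto", "Total", "Nuc")


@dataclass
class SampleMetadata:
    """Bulk-sample metadata: library preparation, extraction, tissue block."""

    sample_id: str
    library_type: str
    rna_extraction: str
    block_id: str
    qc_metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.library_type not in LIBRARY_TYPES:
            raise DataModelError(f"unknown library_type {self.library_type!r}")
        if self.rna_extraction not in RNA_EXTRACTIONS:
            raise DataModelError(f"unknown rna_extraction {self.rna_extraction!r}")
        if not self.block_id:
            raise DataModelError("block_id must be non-empty")


@dataclass
class QCFlag:
    """Outcome of MAD-based QC for one sample."""

    sample_id: str
    status: str  # pass | warn | drop
    failing_metrics: list[str]

    def __post_init__(self) -> None:
        if self.status not in ("pass", "warn", "drop"):
            raise DataModelError(f"invalid QC status {self.status!r}")
        if (self.status == "pass") != (len(self.failing_metrics) == 0):
            raise DataModelError("status 'pass' iff no failing metrics")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression(matrix_path: str | Path,
                    gene_path: str | Path | None = None,
                    unit_path: str | Path | None = None) -> ExpressionMatrix:
    """Read a counts matrix from Matrix Market + annotation TSVs or dense TSV.

    For ``.mtx`` input, ``gene_path`` and ``unit_path`` are line-aligned files
    (one id per line, first column used) matching matrix rows and columns.
    For dense TSV input the first column holds gene ids and the header the
    unit ids; the annotation paths are ignored.
    """
    matrix_path = Path(matrix_path)
    if not matrix_path.exists():
        raise FileNotFoundError(matrix_path)
    if matrix_path.suffix == ".mtx":
        if gene_path is None or unit_path is None:
            raise DataModelError("MTX input requires gene and unit annotation files")
        mat = spio.mmread(str(matrix_path))
        if sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        genes = _read_id_column(gene_path)
        units = _read_id_column(unit_path)
        if len(genes) != mat.shape[0]:
            raise DataModelError(
                f"gene file has {len(genes)} lines but matrix has {mat.shape[0]} rows")
        if len(units) != mat.shape[1]:
            raise DataModelError(
                f"unit file has {len(units)} lines but matrix has {mat.shape[1]} columns")
    else:
        sep = "," if matrix_path.suffix == ".csv" else "\t"
        frame = pd.read_csv(matrix_path, sep=sep, index_col=0)
        mat = frame.to_numpy(dtype=float)
        genes = [str(g) for g in frame.index]
        units = [str(u) for u in frame.columns]
    if np.any(mat < 0):
        raise DataModelError("negative entries in expression input")
    return ExpressionMatrix(mat, genes, units, scale="counts")


def _read_id_column(path: str | Path) -> list[str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def write_expression(expr: ExpressionMatrix, matrix_path: str | Path,
                     gene_path: str | Path | None = None,
                     unit_path: str | Path | None = None) -> None:
    """Write an expression matrix as MTX + TSVs or a dense TSV (by suffix)."""
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if gene_path is None or unit_path is None:
            raise DataModelError("MTX output requires gene and unit annotation paths")
        spio.mmwrite(str(matrix_path), sparse.coo_matrix(expr.values))
        Path(gene_path).write_text("".join(g + "\n" for g in expr.gene_ids))
        Path(unit_path).write_text("".join(u + "\n" for u in expr.unit_ids))
    else:
        sep = "," if matrix_path.suffix == ".csv" else "\t"
        expr.to_frame().to_csv(matrix_path, sep=sep)


# ---------------------------------------------------------------------------
# Normalisation and pseudobulking
# ---------------------------------------------------------------------------

def cpm_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million per unit; all-zero columns are left at zero."""
    if expr.scale != "counts":
        raise DataModelError(f"cpm_normalize expects counts, got {expr.scale}")
    totals = expr.values.sum(axis=0)
    out = np.zeros_like(expr.values)
    nz = totals > 0
    out[:, nz] = expr.values[:, nz] * 1e6 / totals[nz]
    return ExpressionMatrix(out, expr.gene_ids, expr.unit_ids, scale="cpm")


def log_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Elementwise ``log2(x + pseudocount)``; tags the result as log scale."""
    if expr.scale not in ("counts", "cpm"):
        raise DataModelError(f"log_transform expects counts or cpm, got {expr.scale}")
    if pseudocount <= 0:
        raise DataModelError("pseudocount must be positive")
    out = np.log2(expr.values + pseudocount)
    return ExpressionMatrix(out, expr.gene_ids, expr.unit_ids, scale="log")


def pseudobulk(expr: ExpressionMatrix, annotation: CellAnnotation,
               group_by: str = "sample_id") -> ExpressionMatrix:
    """Sum counts over units sharing a ``group_by`` label.

    Emulates bulk libraries from single-nucleus counts; total counts are
    conserved exactly.  Output columns appear in first-occurrence order of the
    group labels.
    """
    if expr.scale != "counts":
        raise DataModelError("pseudobulk is defined on counts")
    if set(expr.unit_ids) != set(annotation.unit_ids):
        raise DataModelError("annotation units do not match expression units")
    per_unit = dict(zip(annotation.unit_ids, annotation.field(group_by)))
    labels = [per_unit[u] for u in expr.unit_ids]
    groups: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    out = np.column_stack([expr.values[:, idx].sum(axis=1) for idx in groups.values()])
    return ExpressionMatrix(out, expr.gene_ids, list(groups), scale="counts")


# ---------------------------------------------------------------------------
# Expression filtering
# ---------------------------------------------------------------------------

def filter_low_expression(expr: ExpressionMatrix,
                          gene_lengths: Mapping[str, float] | Sequence[float] | None = None,
                          min_mean: float = 0.1,
                          ) -> tuple[ExpressionMatrix, np.ndarray]:
    """Drop genes with mean RPKM (or mean CPM when lengths absent) <= min_mean.

    Returns the filtered matrix and a boolean keep-mask over the input genes.
    """
    if expr.scale != "counts":
        raise DataModelError("filter_low_expression expects counts")
    if min_mean < 0:
        raise DataModelError("min_mean must be non-negative")
    totals = expr.values.sum(axis=0)
    nz = totals > 0
    per_million = np.zeros_like(expr.values)
    per_million[:, nz] = expr.values[:, nz] * 1e6 / totals[nz]
    if gene_lengths is not None:
        if isinstance(gene_lengths, Mapping):
            try:
                lengths = np.array([float(gene_lengths[g]) for g in expr.gene_ids])
            except KeyError as exc:
                raise DataModelError(f"gene length missing for {exc.args[0]!r}") from exc
        else:
            lengths = np.asarray(gene_lengths, dtype=float)
            if lengths.shape[0] != expr.n_genes:
                raise DataModelError("gene_lengths misaligned with gene_ids")
        if np.any(lengths <= 0):
            raise DataModelError("gene lengths must be positive")
        # RPKM = CPM / (length in kb)
        per_million = per_million / (lengths[:, None] / 1e3)
    mean_level = per_million.mean(axis=1)
    keep = mean_level > min_mean
    kept = ExpressionMatrix(expr.values[keep, :].copy(),
                            [g for g, k in zip(expr.gene_ids, keep) if k],
                            list(expr.unit_ids), scale="counts")
    logger.info("filter_low_expression: kept %d / %d genes (min_mean=%g)",
                int(keep.sum()), expr.n_genes, min_mean)
    return kept, keep


# ---------------------------------------------------------------------------
# MAD-based QC flagging
# ---------------------------------------------------------------------------

def mad_flag(metrics: pd.DataFrame, k: float = 3.0,
             group_by: Sequence[str] | None = None,
             directions: Mapping[str, str] | None = None,
             drop_at: int = 2) -> list[QCFlag]:
    """Flag samples whose QC metrics are outliers within their stratum.

    Within each stratum (e.g. library type), a sample fails a metric when it
    lies beyond ``median +/- k * MAD`` in that metric's failing direction
    (``low`` = small values fail, ``high`` = large values fail).  The MAD uses
    the 1.4826 consistency constant.  A sample is ``drop`` when at least
    ``drop_at`` metrics fail, ``warn`` when at least one but fewer than
    ``drop_at`` fail, ``pass`` otherwise.

    Parameters
    ----------
    metrics
        sample x metric numeric table indexed by sample id.
    group_by
        Optional per-sample stratum labels aligned to ``metrics`` rows.
    directions
        metric name -> ``low`` | ``high``; metrics not listed default to
        ``low`` (low values fail), matching mapping-rate style metrics.
    """
    if k <= 0:
        raise DataModelError("k must be positive")
    directions = dict(directions or {})
    for m in metrics.columns:
        directions.setdefault(m, "low")
        if directions[m] not in ("low", "high"):
            raise DataModelError(f"direction for {m!r} must be 'low' or 'high'")
        if not np.issubdtype(metrics[m].dtype, np.number):
            raise DataModelError(f"metric {m!r} is not numeric")
    if group_by is None:
        strata = pd.Series(["_all"] * len(metrics), index=metrics.index)
    else:
        strata = pd.Series(list(group_by), index=metrics.index)
    flags: list[QCFlag] = []
    for _, idx in metrics.groupby(strata, sort=False).groups.items():
        block = metrics.loc[idx]
        if len(block) == 0:
            raise DataModelError("empty stratum")
        failing: dict[str, list[str]] = {s: [] for s in block.index}
        for m in block.columns:
            vals = block[m].to_numpy(dtype=float)
            med = float(np.median(vals))
            mad = MAD_CONSTANT * float(np.median(np.abs(vals - med)))
            if directions[m] == "low":
                bad = vals < med - k * mad
            else:
                bad = vals > med + k * mad
            for s, b in zip(block.index, bad):
                if b:
                    failing[s].append(m)
        for s in block.index:
            n_fail = len(failing[s])
            status = "drop" if n_fail >= drop_at else ("warn" if n_fail else "pass")
            flags.append(QCFlag(str(s), status, failing[s]))
    order = {s: i for i, s in enumerate(metrics.index.astype(str))}
    flags.sort(key=lambda f: order[f.sample_id])
    return flags
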