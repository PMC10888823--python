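"""Reference-composition robustness experiments.

Deconvolution results depend on the composition of the single-cell
reference.  Two experiments probe that dependence:

* :func:`equal_proportion_resample` — repeatedly downsample the reference to
  an equal number of cells per type (by default the count of the rarest
  type), re-derive the signature, re-run the estimator, and summarise the
  across-replicate dispersion of the estimates.
* :func:`reference_swap` — run the same bulk data against several reference
  datasets whose label vocabularies are harmonised through a declared
  mapping (e.g. merging endothelial and pericyte labels into one vascular
  class).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import CellAnnotation, DataModelError, ExpressionMatrix, cpm_normalize
from .deconvolution import (Estimator, MarkerSets, ProportionTable,
                            get_estimator, signature_from_reference)


@dataclass
class ResampleResult:
    """Per-replicate proportion tables plus mean and dispersion summaries."""

    replicates: list[ProportionTable]
    seeds: list[int]
    mean: ProportionTable
    dispersion: pd.DataFrame  # unit x cell-type across-replicate sample sd
    n_per_type: int

    @property
    def n_reps(self) -> int:
        return len(self.replicates)

    def mean_dispersion(self) -> float:
        """Average across-replicate sd over all (unit, type) entries."""
        return float(self.dispersion.to_numpy().mean())


def _resolve_estimator(estimator: str | Estimator) -> Estimator:
    if callable(estimator):
        return estimator
    return get_estimator(estimator)


def equal_proportion_resample(ref: ExpressionMatrix, annotation: CellAnnotation,
                              bulk: ExpressionMatrix,
                              estimator: str | Estimator,
                              markers: MarkerSets,
                              n_per_type: int | None = None,
                              n_reps: int = 100,
                              seed: int = 0) -> ResampleResult:
    """Downsample the reference to equal per-type cell counts, repeatedly.

    For replicate r, ``n_per_type`` cells of every type are drawn without
    replacement with seed ``seed + r``, the signature is rebuilt from the
    subset, and the estimator re-run on the bulk data.  ``n_per_type=None``
    uses the size of the rarest type.  The per-replicate seed derivation is
    fixed so any single replicate can be reproduced in isolation.
    """
    if n_reps <= 0:
        raise DataModelError("n_reps must be positive")
    if ref.scale != "counts":
        raise DataModelError("reference must be counts scale")
    fn = _resolve_estimator(estimator)
    by_type: dict[str, list[str]] = {}
    for u, ct in zip(annotation.unit_ids, annotation.cell_type):
        by_type.setdefault(ct, []).append(u)
    min_cells = min(len(v) for v in by_type.values())
    if n_per_type is None:
        n_per_type = min_cells
    if n_per_type > min_cells:
        raise DataModelError(
            f"n_per_type={n_per_type} exceeds rarest type size {min_cells}")
    replicates: list[ProportionTable] = []
    seeds: list[int] = []
    for r in range(n_reps):
        rep_seed = seed + r
        rng = np.random.default_rng(rep_seed)
        chosen: list[str] = []
        types: list[str] = []
        for ct, units in by_type.items():
            picked = rng.choice(len(units), size=n_per_type, replace=False)
            chosen.extend(units[i] for i in sorted(picked))
            types.extend([ct] * n_per_type)
        sub_ref = ref.subset_units(chosen)
        sub_ann = CellAnnotation(chosen, types)
        sig = signature_from_reference(cpm_normalize(sub_ref), sub_ann, markers)
        table = fn(bulk, sig, markers)
        replicates.append(table)
        seeds.append(rep_seed)
    stack = np.stack([t.values.to_numpy(dtype=float) for t in replicates])
    mean_vals = stack.mean(axis=0)
    mean_vals = mean_vals / mean_vals.sum(axis=1, keepdims=True)
    template = replicates[0].values
    mean_table = ProportionTable(
        pd.DataFrame(mean_vals, index=template.index, columns=template.columns),
        method=f"{replicates[0].method}+resample_mean")
    sd = stack.std(axis=0, ddof=1) if n_reps > 1 else np.zeros_like(mean_vals)
    dispersion = pd.DataFrame(sd, index=template.index, columns=template.columns)
    return ResampleResult(replicates, seeds, mean_table, dispersion,
                          int(n_per_type))


def harmonize_annotation(annotation: CellAnnotation,
                         mapping: Mapping[str, str] | None) -> CellAnnotation:
    """Rename / merge cell-type labels through a declared mapping."""
    if not mapping:
        return annotation
    new_types = [mapping.get(ct, ct) for ct in annotation.cell_type]
    return CellAnnotation(annotation.unit_ids, new_types,
                          donor_id=annotation.donor_id,
                          sample_id=annotation.sample_id)


def reference_swap(bulk: ExpressionMatrix,
                   references: Sequence[tuple[ExpressionMatrix, CellAnnotation,
                                              MarkerSets]],
                   estimator: str | Estimator,
                   label_maps: Sequence[Mapping[str, str] | None] | None = None,
                   ) -> list[ProportionTable]:
    """Run the same bulk data against several (harmonised) references.

    ``label_maps[i]`` renames reference i's cell-type labels into the common
    vocabulary before signatures are built; labels that a mapping leaves in
    place must already be common.  Returns one proportion table per
    reference, over that reference's harmonised type set.
    """
    fn = _resolve_estimator(estimator)
    if label_maps is None:
        label_maps = [None] * len(references)
    if len(label_maps) != len(references):
        raise DataModelError("label_maps length must match references")
    tables: list[ProportionTable] = []
    for (ref, ann, markers), lmap in zip(references, label_maps):
        ann = harmonize_annotation(ann, lmap)
        ref_cpm = cpm_normalize(ref) if ref.scale == "counts" else ref
        sig = signature_from_reference(ref_cpm, ann, markers)
        tables.append(fn(bulk, sig, markers))
    return tables
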