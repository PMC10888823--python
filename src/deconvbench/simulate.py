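"""Synthetic data generation for every stage of the benchmark.

Three generators emulate the structures the benchmark consumes:

* :func:`simulate_reference` — a multi-donor single-nucleus reference with
  seven cortical broad cell types, log-normal baseline gene means, a set of
  planted marker genes per type (fold-elevated only in that type), and
  negative-binomial counts.
* :func:`simulate_bulk` — bulk mixtures with known cell-count composition.
  Expected expression for a sample is a composition-weighted combination of
  type mean profiles, weighted additionally by per-type RNA content (size)
  factors, then distorted by per-gene multiplicative library-preparation
  biases (emulating genes differentially quantified between mRNA-enrichment
  and rRNA-depletion libraries) and Poisson or negative-binomial noise.
* :func:`simulate_cells_table` — segmented-cell tables as an imaging
  pipeline would export: per-cell phenotype, nuclear area, puncta count,
  with a controllable fraction of oversized segmentation artefacts.

All generators are deterministic under a fixed seed.  Defaults mirror a
human dorsolateral prefrontal cortex setting: excitatory neurons the most
common type, microglia the rarest, and neurons carrying more RNA per cell
than glia.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (CellAnnotation, DataModelError, ExpressionMatrix,
                         SampleMetadata)

#: broad cortical cell types, most common (Excit) to rarest (Micro) mixed in
DEFAULT_CELL_TYPES = ("Astro", "EndoMural", "Micro", "Oligo", "OPC",
                      "Excit", "Inhib")

#: reference nuclei composition; Excit most common (0.44), Micro rarest (0.03)
DEFAULT_REF_COMPOSITION = {
    "Astro": 0.10, "EndoMural": 0.05, "Micro": 0.03, "Oligo": 0.20,
    "OPC": 0.05, "Excit": 0.44, "Inhib": 0.13,
}

#: per-type RNA content multipliers: neurons are larger and carry more RNA
DEFAULT_SIZE_FACTORS = {
    "Astro": 1.0, "EndoMural": 0.8, "Micro": 0.7, "Oligo": 0.9,
    "OPC": 0.9, "Excit": 1.8, "Inhib": 1.5,
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic reference / bulk / imaging generators."""

    n_genes: int = 2000
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    cells_per_type: int | Mapping[str, int] = 300
    n_donors: int = 4
    n_markers_per_type: int = 25
    marker_fold: float = 8.0
    baseline_log_mean: float = 1.0   # log-normal params of baseline mean CPM-ish level
    baseline_log_sd: float = 1.0
    dispersion: float = 10.0         # NB inverse-dispersion (size); var = mu + mu^2/size
    size_factors: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_FACTORS))
    # bulk side
    n_bulk_samples: int = 24
    library_types: tuple[str, ...] = ("polyA", "RiboZeroGold")
    bulk_library_size: float = 1e6
    true_props: np.ndarray | None = None    # explicit n_samples x n_types
    dirichlet_alpha: float = 5.0
    noise: str = "poisson"                  # poisson | nb | none
    bulk_dispersion: float = 50.0
    # planted library bias (emulates differential quantification)
    bias_library: str | None = None         # library type receiving the bias
    bias_target_type: str | None = None     # whose markers are biased
    bias_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.n_markers_per_type * len(self.cell_types) > self.n_genes:
            raise DataModelError("more planted markers than genes")
        if self.marker_fold <= 0:
            raise DataModelError("marker_fold must be positive")
        for ct in self.cell_types:
            if ct not in self.size_factors:
                raise DataModelError(f"missing size factor for {ct!r}")

    def cells_for(self, cell_type: str) -> int:
        if isinstance(self.cells_per_type, Mapping):
            return int(self.cells_per_type[cell_type])
        return int(self.cells_per_type)


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a synthetic dataset."""

    type_means: pd.DataFrame            # types x genes expected expression
    marker_map: dict[str, str]          # gene -> planted type
    cell_fractions: pd.DataFrame | None = None   # samples x types (counts)
    rna_fractions: pd.DataFrame | None = None    # samples x types (size-weighted)
    library_bias: dict[str, np.ndarray] | None = None  # lib -> per-gene factor

    def planted_markers(self, cell_type: str) -> list[str]:
        return [g for g, ct in self.marker_map.items() if ct == cell_type]


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{str(i).zfill(width)}" for i in range(n)]


def _nb_counts(rng: np.random.Generator, mu: np.ndarray,
               size: float) -> np.ndarray:
    """Negative-binomial draws with mean mu and inverse-dispersion size."""
    mu = np.maximum(mu, 1e-12)
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_reference(config: GeneratorConfig, seed: int = 0,
                       truth: SyntheticTruth | None = None,
                       ) -> tuple[ExpressionMatrix, CellAnnotation, SyntheticTruth]:
    """Simulate a single-nucleus reference with planted marker genes.

    Gene g in type k has mean ``baseline_g * marker_fold`` when g is planted
    as a marker for k, and ``baseline_g`` otherwise; counts are
    negative-binomial around those means.  Passing an existing ``truth``
    reuses its expected means and marker map, producing a technical-replicate
    reference (same underlying profiles, fresh count sampling).
    """
    rng = np.random.default_rng(seed)
    genes = _gene_ids(config.n_genes)
    types = list(config.cell_types)
    if truth is not None:
        mu = truth.type_means.to_numpy(dtype=float)
        if mu.shape != (len(types), config.n_genes):
            raise DataModelError("supplied truth does not match config shape")
        genes = list(truth.type_means.columns)
        marker_map = dict(truth.marker_map)
    else:
        baseline = rng.lognormal(config.baseline_log_mean,
                                 config.baseline_log_sd, size=config.n_genes)
        # plant disjoint marker blocks on randomly chosen genes
        order = rng.permutation(config.n_genes)
        marker_map = {}
        mu = np.tile(baseline, (len(types), 1))  # types x genes
        pos = 0
        for ct in types:
            block = order[pos:pos + config.n_markers_per_type]
            pos += config.n_markers_per_type
            mu[types.index(ct), block] *= config.marker_fold
            for gi in block:
                marker_map[genes[gi]] = ct
    cells, labels, donors = [], [], []
    for ct in types:
        n_cells = config.cells_for(ct)
        counts = _nb_counts(rng, np.tile(mu[types.index(ct)], (n_cells, 1)).T,
                            config.dispersion)
        cells.append(counts)
        labels.extend([ct] * n_cells)
        donors.extend([f"D{(i % config.n_donors) + 1}" for i in range(n_cells)])
    values = np.concatenate(cells, axis=1).astype(float)
    unit_ids = [f"cell{str(i).zfill(6)}" for i in range(values.shape[1])]
    expr = ExpressionMatrix(values, genes, unit_ids, scale="counts")
    ann = CellAnnotation(unit_ids, labels, donor_id=donors,
                         sample_id=[d for d in donors])
    truth = SyntheticTruth(
        type_means=pd.DataFrame(mu, index=types, columns=genes),
        marker_map=marker_map,
    )
    return expr, ann, truth


def _draw_compositions(config: GeneratorConfig,
                       rng: np.random.Generator) -> np.ndarray:
    n_types = len(config.cell_types)
    if config.true_props is not None:
        props = np.asarray(config.true_props, dtype=float)
        if props.ndim != 2 or props.shape[1] != n_types:
            raise DataModelError("true_props must be n_samples x n_types")
        if not np.allclose(props.sum(axis=1), 1.0, atol=1e-8):
            raise DataModelError("true proportion rows must sum to 1")
        return props
    return rng.dirichlet([config.dirichlet_alpha] * n_types,
                         size=config.n_bulk_samples)


def library_bias_vectors(config: GeneratorConfig, truth: SyntheticTruth,
                         ) -> dict[str, np.ndarray]:
    """Per-gene multiplicative bias factors for each library type.

    All factors default to 1; when a planted bias is configured, the markers
    of ``bias_target_type`` are multiplied by ``bias_factor`` in the
    ``bias_library`` library only, emulating over-quantification of that
    type's markers in one library preparation.
    """
    genes = list(truth.type_means.columns)
    bias = {lib: np.ones(len(genes)) for lib in config.library_types}
    if config.bias_library is not None and config.bias_factor != 1.0:
        if config.bias_library not in config.library_types:
            raise DataModelError(f"unknown bias library {config.bias_library!r}")
        if config.bias_target_type is None:
            raise DataModelError("bias_target_type required with bias_library")
        planted = set(truth.planted_markers(config.bias_target_type))
        if not planted:
            raise DataModelError(
                f"no planted markers for {config.bias_target_type!r}")
        mask = np.array([g in planted for g in genes])
        bias[config.bias_library][mask] *= config.bias_factor
    return bias


def simulate_bulk(config: GeneratorConfig, truth: SyntheticTruth, seed: int = 0,
                  ) -> tuple[ExpressionMatrix, list[SampleMetadata], SyntheticTruth]:
    """Simulate bulk mixtures from a reference truth.

    Each tissue block contributes one sample per configured library type,
    all sharing the block's true cell-count composition c.  Expected
    expression is ``bias_g^(lib) * sum_k c_k * s_k * mu_{g,k}`` rescaled to
    the target library size, with Poisson (default) or negative-binomial
    counts.  Because mixing weights are ``c_k * s_k``, an RNA-matching
    estimator recovers the RNA fractions ``normalize(c * s)``; dividing by
    the size factors recovers ``c``.
    """
    rng = np.random.default_rng(seed)
    types = list(config.cell_types)
    genes = list(truth.type_means.columns)
    mu = truth.type_means.to_numpy(dtype=float)  # types x genes
    comps = _draw_compositions(config, rng)
    n_blocks = comps.shape[0]
    sizes = np.array([config.size_factors[ct] for ct in types])
    rna = comps * sizes
    rna = rna / rna.sum(axis=1, keepdims=True)
    bias = library_bias_vectors(config, truth)
    cols, meta, sample_ids = [], [], []
    extraction = "Total"
    for b in range(n_blocks):
        block_id = f"B{str(b + 1).zfill(2)}"
        weights = comps[b] * sizes
        base = weights @ mu  # per-gene expected expression
        for lib in config.library_types:
            lam = base * bias[lib]
            total = lam.sum()
            if total <= 0:
                raise DataModelError("degenerate all-zero bulk profile")
            lam = lam * config.bulk_library_size / total
            if config.noise == "poisson":
                counts = rng.poisson(lam)
            elif config.noise == "nb":
                counts = _nb_counts(rng, lam, config.bulk_dispersion)
            elif config.noise == "none":
                counts = lam
            else:
                raise DataModelError(f"unknown noise model {config.noise!r}")
            sid = f"{block_id}_{lib}"
            sample_ids.append(sid)
            cols.append(np.asarray(counts, dtype=float))
            meta.append(SampleMetadata(sid, lib, extraction, block_id))
    values = np.column_stack(cols)
    expr = ExpressionMatrix(values, genes, sample_ids, scale="counts")
    out_truth = SyntheticTruth(
        type_means=truth.type_means,
        marker_map=dict(truth.marker_map),
        cell_fractions=pd.DataFrame(
            np.repeat(comps, len(config.library_types), axis=0),
            index=sample_ids, columns=types),
        rna_fractions=pd.DataFrame(
            np.repeat(rna, len(config.library_types), axis=0),
            index=sample_ids, columns=types),
        library_bias=bias,
    )
    return expr, meta, out_truth


# ---------------------------------------------------------------------------
# Segmented-cell (imaging) tables
# ---------------------------------------------------------------------------

#: per-type nuclear-area log-normal parameters (median area in um^2, log sd)
DEFAULT_AREA_PARAMS = {
    "Astro": (35.0, 0.3), "EndoMural": (25.0, 0.3), "Micro": (22.0, 0.3),
    "Oligo": (28.0, 0.3), "OPC": (26.0, 0.3), "Excit": (55.0, 0.3),
    "Inhib": (45.0, 0.3), "other": (30.0, 0.35),
}

#: per-type mean puncta counts of the total-RNA probe
DEFAULT_PUNCTA_MEANS = {
    "Astro": 8.0, "EndoMural": 5.0, "Micro": 4.0, "Oligo": 6.0,
    "OPC": 6.0, "Excit": 20.0, "Inhib": 15.0, "other": 8.0,
}


def simulate_cells_table(composition: Mapping[str, float], n_cells: int,
                         seed: int = 0,
                         section_id: str = "S1",
                         combination: str = "Star",
                         area_params: Mapping[str, tuple[float, float]] | None = None,
                         puncta_means: Mapping[str, float] | None = None,
                         oversize_fraction: float = 0.0,
                         max_radius: float = 5.0) -> pd.DataFrame:
    """Simulate a segmented-cell table with known phenotype composition.

    ``composition`` maps phenotype labels (use ``"other"`` for unlabeled
    cells) to probabilities summing to 1.  Nuclear areas are log-normal per
    type, puncta counts Poisson per type.  An ``oversize_fraction`` of cells
    is planted with nuclear radius above ``max_radius`` to exercise the
    segmentation-artefact filter; all remaining cells are kept within the
    radius bound.
    """
    labels = list(composition)
    p = np.array([composition[k] for k in labels], dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise DataModelError("composition must be non-negative and sum to 1")
    if not 0 <= oversize_fraction < 1:
        raise DataModelError("oversize_fraction must be in [0, 1)")
    area_params = dict(area_params or DEFAULT_AREA_PARAMS)
    puncta_means = dict(puncta_means or DEFAULT_PUNCTA_MEANS)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_cells, p)
    phen, areas, puncta = [], [], []
    for label, n in zip(labels, counts):
        med, sd = area_params.get(label, DEFAULT_AREA_PARAMS["other"])
        lam = puncta_means.get(label, DEFAULT_PUNCTA_MEANS["other"])
        phen.extend([label] * n)
        areas.append(rng.lognormal(np.log(med), sd, size=n))
        puncta.append(rng.poisson(lam, size=n))
    areas_arr = np.concatenate(areas) if areas else np.array([])
    puncta_arr = np.concatenate(puncta) if puncta else np.array([])
    # keep ordinary cells within the radius bound (segmentation size limit)
    max_area = np.pi * max_radius ** 2
    areas_arr = np.minimum(areas_arr, 0.99 * max_area)
    n_over = int(round(oversize_fraction * n_cells))
    over_idx = rng.choice(n_cells, size=n_over, replace=False) if n_over else []
    for i in over_idx:
        r = max_radius * rng.uniform(1.1, 2.0)
        areas_arr[i] = np.pi * r ** 2
    table = pd.DataFrame({
        "section_id": section_id,
        "combination": combination,
        "phenotype": phen,
        "nuclear_area": areas_arr,
        "puncta_count": puncta_arr.astype(int),
    })
    return table.sample(frac=1.0, random_state=int(rng.integers(2 ** 31 - 1))
                        ).reset_index(drop=True)
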