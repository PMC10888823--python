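"""End-to-end benchmark recipe: markers -> deconvolve -> collapse -> evaluate.

:func:`run_benchmark` ties the stages together for a cartesian grid of
marker rules and estimators, writes every artifact to an output directory,
and returns a manifest listing each file with a checksum so a rerun under
the same seed can be verified byte-for-byte.  A failing estimator is
recorded in the manifest without aborting the remaining combinations.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import CellAnnotation, DataModelError, ExpressionMatrix, \
    cpm_normalize, log_transform
from .deconvolution import (ProportionTable, cell_size_adjust,
                            collapse_cell_types, get_estimator,
                            signature_from_reference)
from .evaluation import compare_proportions
from .markers import build_marker_sets, marker_stats
from .simulate import GeneratorConfig, simulate_bulk, simulate_reference

logger = logging.getLogger(__name__)


@dataclass
class BenchmarkConfig:
    """Configuration of one benchmark run.

    When ``generator`` is given, the reference, bulk, and truth are
    simulated under ``seed``; otherwise pre-built objects must be supplied.
    """

    marker_rules: Sequence[tuple[str, Mapping]] = (("mean_ratio_top_n", {"n": 25}),)
    estimators: Sequence[str] = ("nnls",)
    cell_sizes: Mapping[str, float] | None = None
    collapse_map: Mapping[str, str] | None = None
    seed: int = 0
    generator: GeneratorConfig | None = None
    out_dir: str | Path = "benchmark_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BenchmarkConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        rules = [(r["rule"], r.get("params", {}))
                 for r in raw.pop("marker_rules", [{"rule": "mean_ratio_top_n",
                                                    "params": {"n": 25}}])]
        cfg = cls(marker_rules=rules, **raw)
        if gen is not None:
            cfg.generator = GeneratorConfig(**gen)
        return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_benchmark(config: BenchmarkConfig,
                  ref: ExpressionMatrix | None = None,
                  annotation: CellAnnotation | None = None,
                  bulk: ExpressionMatrix | None = None,
                  truth: ProportionTable | None = None) -> dict:
    """Run the full grid of marker rules x estimators and write artifacts.

    Returns the manifest dict (also written to ``manifest.json``):
    per-combination output files with sha256 checksums, evaluation metrics,
    and any per-combination failures.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.generator is not None:
        ref, annotation, ref_truth = simulate_reference(config.generator,
                                                        seed=config.seed)
        bulk, _, bulk_truth = simulate_bulk(config.generator, ref_truth,
                                            seed=config.seed + 1)
        truth = ProportionTable(bulk_truth.cell_fractions, method="truth")
    if ref is None or annotation is None or bulk is None:
        raise DataModelError("run_benchmark needs a generator or explicit inputs")
    ref_cpm = cpm_normalize(ref)
    ref_log = log_transform(ref_cpm)
    bulk_cpm = cpm_normalize(bulk)
    stats = marker_stats(ref_cpm, ref_log, annotation)
    stats_path = out_dir / "marker_stats.tsv"
    stats.to_csv(stats_path, sep="\t", index=False)
    manifest: dict = {"seed": config.seed, "outputs": [], "evaluations": [],
                      "failures": []}
    manifest["outputs"].append({"path": stats_path.name,
                                "sha256": _checksum(stats_path)})
    common = set(bulk.gene_ids) & set(ref.gene_ids)
    for rule, params in config.marker_rules:
        markers = build_marker_sets(stats, rule, params, common_genes=common)
        tag = rule if not params else rule + "_" + "_".join(
            f"{k}{v}" for k, v in sorted(params.items()))
        mpath = out_dir / f"markers_{tag}.tsv"
        markers.write(mpath)
        manifest["outputs"].append({"path": mpath.name,
                                    "sha256": _checksum(mpath)})
        sig = signature_from_reference(ref_cpm, annotation, markers)
        for est_name in config.estimators:
            try:
                est = get_estimator(est_name)
                props = est(bulk_cpm, sig, markers)
                props.marker_set = tag
                if config.cell_sizes is not None:
                    props = cell_size_adjust(props, config.cell_sizes)
                if config.collapse_map:
                    props = collapse_cell_types(props, config.collapse_map)
                ppath = out_dir / f"props_{est_name}_{tag}.tsv"
                props.write(ppath)
                manifest["outputs"].append({"path": ppath.name,
                                            "sha256": _checksum(ppath)})
                if truth is not None:
                    eval_truth = truth
                    if config.collapse_map:
                        eval_truth = collapse_cell_types(truth,
                                                         config.collapse_map)
                    res = compare_proportions(props, eval_truth)[0]
                    manifest["evaluations"].append({
                        "estimator": est_name, "marker_set": tag,
                        "cor": res.cor, "rmse": res.rmse, "rrmse": res.rrmse,
                        "n_pairs": res.n_pairs,
                    })
            except Exception as exc:  # keep other combinations running
                logger.exception("estimator %s failed on %s", est_name, tag)
                manifest["failures"].append({"estimator": est_name,
                                             "marker_set": tag,
                                             "error": str(exc)})
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
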