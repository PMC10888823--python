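import numpy as np
import pytest

import deconvbench as db


@pytest.fixture(scope="session")
def small_config():
    """Small but non-trivial generator configuration shared across tests."""
    return db.GeneratorConfig(n_genes=400, cells_per_type=60,
                              n_markers_per_type=10, marker_fold=8.0,
                              n_bulk_samples=6)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return db.simulate_reference(small_config, seed=11)


@pytest.fixture(scope="session")
def small_bulk(small_config, small_reference):
    _, _, truth = small_reference
    return db.simulate_bulk(small_config, truth, seed=12)


@pytest.fixture(scope="session")
def small_markers(small_reference):
    ref, ann, _ = small_reference
    cpm = db.cpm_normalize(ref)
    stats = db.marker_stats(cpm, db.log_transform(cpm), ann)
    return db.build_marker_sets(stats, "mean_ratio_top_n", {"n": 10})


def random_expression(rng, n_genes=30, n_units=10, scale="counts"):
    vals = rng.integers(0, 50, size=(n_genes, n_units)).astype(float)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    units = [f"u{i:03d}" for i in range(n_units)]
    return db.ExpressionMatrix(vals, genes, units, scale=scale)
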