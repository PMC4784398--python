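"""Shared fixtures: one small synthetic screen reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from crispri_screen.simulate import (
    SimConfig,
    guide_potency,
    simulate_counts,
    simulate_library,
    simulate_locus,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=42, n_genes=4, n_guides_per_gene=8, depth=50_000, replicates=2)


@pytest.fixture(scope="session")
def small_locus(small_cfg):
    genome, annotations, (nuc, atac) = simulate_locus(small_cfg)
    return genome, annotations, nuc, atac


@pytest.fixture(scope="session")
def small_library(small_cfg, small_locus):
    genome, annotations, nuc, _ = small_locus
    return simulate_library(small_cfg, genome, annotations, nuc)


@pytest.fixture(scope="session")
def small_screen(small_cfg, small_library):
    matrix, truth = simulate_counts(small_cfg, small_library)
    return matrix, truth


@pytest.fixture()
def toy_counts():
    """Three guides, one pool, a +/-ATc pair: hand-checkable numbers."""
    from crispri_screen.core import CountMatrix

    counts = pd.DataFrame(
        {"s_plus": [7, 15, 31], "s_minus": [100, 100, 100]},
        index=pd.Index(["g1", "g2", "g3"], name="guide_id"),
    )
    samples = pd.DataFrame(
        {
            "sample": ["s_plus", "s_minus"],
            "pool": ["p", "p"],
            "atc": [True, False],
            "compound": ["DMSO", "DMSO"],
            "concentration": [1.0, 1.0],
            "replicate": [1, 1],
        }
    )
    return CountMatrix(counts, samples)


@pytest.fixture(scope="session")
def small_potency(small_cfg, small_library):
    return guide_potency(small_cfg, small_library)
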