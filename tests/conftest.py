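"""Shared fixtures: small synthetic genomes reused across test modules."""

from __future__ import annotations

import pytest

from homeodyn import homology
from homeodyn.containers import SampleDesign
from homeodyn.synthetic_data import SimulationParams, simulate_counts, simulate_subgenomes

SMALL_PARAMS = SimulationParams(
    n_chrom=1,
    genes_per_chrom=40,
    mean_gene_len=600,
    substitution_rate=0.0,
    n_insertions_a=3,
    n_deletions_b=2,
    n_insertions_b=3,
    n_deletions_a=2,
    seed=101,
)


@pytest.fixture(scope="session")
def small_sim():
    """Noise-free 40-gene genome pair with 3 insertions / 2 losses per side."""
    ann_a, ann_b, truth = simulate_subgenomes(SMALL_PARAMS)
    return ann_a, ann_b, truth


@pytest.fixture(scope="session")
def small_classified(small_sim):
    """Homoeolog table + specific records + summary on the small fixture."""
    ann_a, ann_b, truth = small_sim
    table, specific, summary = homology.identify_homoeologs(ann_a, ann_b)
    return ann_a, ann_b, truth, table, specific, summary


@pytest.fixture(scope="session")
def small_counts(small_sim):
    ann_a, ann_b, truth = small_sim
    design = SampleDesign()
    cm_a, cm_b = simulate_counts(truth, design, SMALL_PARAMS, annotations=(ann_a, ann_b))
    return cm_a, cm_b, truth, design
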