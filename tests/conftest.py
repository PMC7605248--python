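"""Shared fixtures: one small simulated study reused across test modules.

All fixtures are generated programmatically from seeds; nothing is read
from disk.
"""
from __future__ import annotations

import pytest

from techimera import pipeline, refprep, simdata


@pytest.fixture(scope="session")
def sim():
    """80 kb genome, 8 genes, 3 LTR transposon subfamilies, 6 insertions
    (mixed orientation/placement, frequencies 0.5/1.0), 10 individuals."""
    return simdata.simulate_genome(
        n_genes=8,
        n_te_subfamilies=3,
        genome_len=80_000,
        n_insertions=6,
        n_individuals=10,
        seed=1,
        splicing_fraction=0.4,
    )


@pytest.fixture(scope="session")
def bundle(sim):
    masked = refprep.mask_genome(sim.genome, sim.te_library)
    return refprep.build_combined_reference(masked, sim.te_library)


@pytest.fixture(scope="session")
def annotation(sim):
    return refprep.build_annotation_index(sim.gff3_text, from_string=True)


@pytest.fixture(scope="session")
def gdna_result(sim, bundle, annotation):
    pairs = simdata.simulate_gdna_reads(sim, coverage=15, seed=2)
    return pipeline.detect_sample(pairs, bundle, mode="gdna", annotation=annotation)


@pytest.fixture(scope="session")
def cdna_sim(sim):
    pairs, truth = simdata.simulate_cdna_reads(
        sim, mean_fragments_per_gene=400, seed=3
    )
    return pairs, truth


@pytest.fixture(scope="session")
def cdna_result(sim, bundle, annotation, cdna_sim):
    pairs, _ = cdna_sim
    return pipeline.detect_sample(pairs, bundle, mode="cdna", annotation=annotation)
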