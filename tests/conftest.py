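"""Shared fixtures: one small synthetic study reused across test modules.

Everything is generated at test time from fixed seeds; the session-scoped
fixtures exist because planting hairpins and simulating four libraries
is the expensive part of the suite.
"""

import numpy as np
import pytest

from mirseq import simulate
from mirseq.simulate import LibrarySpec, SimulationDesign


def small_design(seed=11, n_mirnas=8, reads=20_000):
    return SimulationDesign(
        n_mirnas=n_mirnas,
        n_scaffolds=2,
        scaffold_length=40_000,
        libraries=[
            LibrarySpec("LC", "control", "leaf", reads),
            LibrarySpec("LS", "stress", "leaf", reads),
            LibrarySpec("RC", "control", "root", reads),
            LibrarySpec("RS", "stress", "root", reads),
        ],
        seed=seed,
    )


@pytest.fixture(scope="session")
def design():
    return small_design()


@pytest.fixture(scope="session")
def study(design):
    """Genome with planted hairpins plus references and annotation."""
    rng = np.random.default_rng(design.seed)
    genome = simulate.generate_genome(design, rng)
    genome, planted = simulate.plant_hairpins(genome, design, rng)
    ncrna = simulate.make_ncrna_refs(design, rng)
    annot = simulate.make_gene_annotation(design, genome, planted, rng)
    return {"design": design, "genome": genome, "planted": planted,
            "ncrna": ncrna, "annot": annot}


@pytest.fixture(scope="session")
def libraries(study):
    """Simulated FASTQ-equivalent reads and the miRNA truth table."""
    rng = np.random.default_rng(study["design"].seed + 4)
    reads, truth = simulate.simulate_libraries(
        study["planted"], study["design"], study["genome"],
        study["ncrna"], study["annot"], rng)
    return {"reads": reads, "truth": truth}
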