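import numpy as np
import pytest

from cubkit import bacterial_code, gene_index_table, qc_filter
from cubkit.indices import build_reference_weights
from cubkit.seq_ingest import CodingSequence
from cubkit.synthetic import generate_genome, preset_suite


@pytest.fixture(scope="session")
def code():
    return bacterial_code()


def genome_sequences(preset: str, seed: int = 11, n_genes: int = 300):
    spec = preset_suite(seed=seed, n_genes=n_genes)[preset]
    records, truth = generate_genome(spec)
    seqs = [CodingSequence(i, s, genome=preset) for i, s in records]
    return seqs, truth, spec


@pytest.fixture(scope="session")
def mutation_genome():
    return genome_sequences("mutation-dominated")


@pytest.fixture(scope="session")
def selection_genome():
    return genome_sequences("selection-dominated")


@pytest.fixture(scope="session")
def null_genome():
    return genome_sequences("null-uniform")


def index_table_for(seqs):
    retained, _ = qc_filter(seqs)
    weights = build_reference_weights(retained, selector="iterative")
    return retained, gene_index_table(retained, weights)


@pytest.fixture(scope="session")
def mutation_table(mutation_genome):
    seqs, truth, _ = mutation_genome
    retained, table = index_table_for(seqs)
    return retained, table, truth


@pytest.fixture(scope="session")
def selection_table(selection_genome):
    seqs, truth, _ = selection_genome
    retained, table = index_table_for(seqs)
    return retained, table, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
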