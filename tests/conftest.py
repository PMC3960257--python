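import numpy as np
import pytest

import plastidkit as pk


@pytest.fixture(scope="session")
def quad_genome():
    """A small quadripartite genome with its planted partition."""
    return pk.make_plastome(lsc_len=5000, ssc_len=800, ir_len=1000, seed=7)


@pytest.fixture(scope="session")
def annotated_genome():
    """Genome + gene catalogue including an intron gene, an IR duplicate and a
    trans-spliced gene."""
    genome, partition = pk.make_plastome(6000, 1500, 1200, seed=3)
    genes, truth = pk.plant_genes(
        genome, partition, n_genes=6, n_intron_genes=1, n_ir_duplicates=1,
        include_trans_spliced=True, seed=3,
    )
    return genome, partition, genes, truth


def random_seq(seed: int, length: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))
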