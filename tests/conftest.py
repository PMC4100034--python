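import numpy as np
import pytest

from cubkit import simulate
from cubkit.seqio import CodingSequence, count_codons


@pytest.fixture(scope="session")
def trna_fixture():
    return simulate.generate_trna_fixture()


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced synthetic scenario shared across tests (seed fixed)."""
    return simulate.generate_dataset(simulate.small_config(seed=11))


@pytest.fixture(scope="session")
def default_dataset():
    """The default 1,500-gene synthetic scenario."""
    return simulate.generate_dataset(simulate.GeneratorConfig(seed=7))


def random_cds(rng: np.random.Generator, n_codons: int = 100, gene_id: str = "g") -> CodingSequence:
    """A random valid CDS drawn uniformly over sense codons."""
    from cubkit.genetic_code import SENSE_CODONS

    codons = rng.choice(len(SENSE_CODONS), size=n_codons)
    return CodingSequence(gene_id, "".join(SENSE_CODONS[i] for i in codons))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
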