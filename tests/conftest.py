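import numpy as np
import pytest

from rnasig import GenomeRecord, write_fasta
from rnasig.synthetic import SyntheticSpec, generate_iid_genome


@pytest.fixture
def toy_record():
    return GenomeRecord(id="toy", sequence="GGAUGAAAUAAGG")


@pytest.fixture
def toy_fasta(tmp_path, toy_record):
    path = tmp_path / "toy.fasta"
    write_fasta([toy_record], path)
    return path


@pytest.fixture(scope="session")
def flavivirus_like_genome():
    """~10.8 kb i.i.d. genome at the purine-rich composition, fixed seed."""
    return generate_iid_genome(SyntheticSpec(seed=20160608))


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
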