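import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from epitopescan import SimulationConfig, generate_proteome, tile_proteome


def make_records(seqs: dict[str, str]) -> list[SeqRecord]:
    return [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]


@pytest.fixture(scope="session")
def small_library():
    """A small random library (~500 peptides) reused across tests."""
    cfg = SimulationConfig(seed=11, n_proteins=20, protein_length=(60, 120))
    records = generate_proteome(cfg)
    return tile_proteome(records, k=16, step=3), cfg


@pytest.fixture(scope="session")
def big_library():
    """~1e5-peptide library matching the discovery-scale simulations."""
    cfg = SimulationConfig(seed=7, n_proteins=1700, protein_length=(150, 250))
    records = generate_proteome(cfg)
    lib = tile_proteome(records, k=16, step=3)
    assert len(lib) > 90_000
    return lib, cfg


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
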