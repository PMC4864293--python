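import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from polyweave import _seq
from polyweave.reads import Reads
from polyweave.simgenome import SimConfig, simulate_progenitors


@pytest.fixture
def rng():
    return np.random.default_rng(20160511)


@pytest.fixture(scope="session")
def small_progenitors():
    cfg = SimConfig(seed=42, genome_length=20_000,
                    progenitor_divergence=0.01)
    return cfg, simulate_progenitors(cfg)


def make_reads(seqs: list[str], names=None) -> Reads:
    names = names or [f"r{i}" for i in range(len(seqs))]
    return Reads.from_sequences(names, seqs)


def genome_of(seq: str, chrom: str = "chr1"):
    return {chrom: _seq.encode(seq)}
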