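from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from apasites.io import Genome
from apasites.simulate import SimConfig, simulate_reads, simulate_reference


@pytest.fixture
def toy_genome() -> Genome:
    return Genome({"chr1": "AACCGGTT", "chr2": "ACGTACGTACGT"})


@pytest.fixture(scope="session")
def sim_reference():
    """Default stated-world reference: 20 genes x 2 sites, seed 1."""
    return simulate_reference(SimConfig(seed=1))


@pytest.fixture(scope="session")
def sim_reads(sim_reference):
    return simulate_reads(sim_reference)


def make_window_genome(window: str, pad: str = "G") -> tuple[Genome, int]:
    """Genome whose plus-strand downstream window of a site is `window`:
    returns (genome, 1-based cleavage position)."""
    seq = pad * 10 + "C" + window
    return Genome({"chrW": seq}), 11
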