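from __future__ import annotations

import numpy as np
import pytest

from cxmotifs import ProteinRecord, make_topology

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(STANDARD_AA[i] for i in rng.integers(0, 20, size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230816)


@pytest.fixture
def simple_topology():
    """A compact connexin-like topology: 230 residues, 9 segments."""
    return make_topology("P1", {
        "NT": 20, "TM1": 20, "E1": 30, "TM2": 20, "IL": 40,
        "TM3": 20, "E2": 30, "TM4": 20, "CT": 30,
    })


def protein_for(topology, sequence: str) -> ProteinRecord:
    assert len(sequence) == topology.length
    return ProteinRecord(id=topology.protein_id, sequence=sequence)
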