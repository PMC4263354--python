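"""Shared fixtures: the E. coli/Trg preset and its steric landmarks."""

import pytest

from memrec import (
    preset,
    min_center_distance,
    FACE_ON,
    TIP_ON,
    CLEARANCE_NM,
)


@pytest.fixture(scope="session")
def ecoli():
    """(MembraneParams, InclusionShape) for the E. coli/Trg preset."""
    return preset("ecoli")


@pytest.fixture(scope="session")
def ecoli_params(ecoli):
    return ecoli[0]


@pytest.fixture(scope="session")
def trg(ecoli):
    return ecoli[1]


@pytest.fixture(scope="session")
def d_face(trg):
    """Steric-minimum centre distance of the face-on pair (0.8 nm clearance)."""
    return min_center_distance(trg, trg, FACE_ON, CLEARANCE_NM)


@pytest.fixture(scope="session")
def d_tip(trg):
    """Steric-minimum centre distance of the tip-on pair (0.8 nm clearance)."""
    return min_center_distance(trg, trg, TIP_ON, CLEARANCE_NM)
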