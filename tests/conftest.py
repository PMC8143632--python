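import numpy as np
import pytest

from apmskit.io import (
    CONTROL,
    PeptideEvidence,
    ProteinDatabase,
    ProteinRecord,
    RunRecord,
    StudyDesign,
)


@pytest.fixture
def tiny_proteins() -> ProteinDatabase:
    """Three proteins with lengths 300, 100 and 12 (sequences are arbitrary
    but consistent: lengths equal residue counts)."""
    return ProteinDatabase(
        [
            ProteinRecord("P1", "MKVLAEGHTSWQ" * 25),   # 300 residues
            ProteinRecord("P2", "MAGKLEVHTSWQ" * 8 + "MKVR"),  # 100
            ProteinRecord("P3", "MKKAYWLVEGHR"),        # 12
        ]
    )


@pytest.fixture
def simple_design() -> StudyDesign:
    return StudyDesign(
        [
            RunRecord("b1_r1", "bait1", 1),
            RunRecord("b1_r2", "bait1", 2),
            RunRecord("b1_r3", "bait1", 3),
            RunRecord("ctrl_r1", CONTROL, 1),
            RunRecord("ctrl_r2", CONTROL, 2),
            RunRecord("ctrl_r3", CONTROL, 3),
        ]
    )


def make_evidence(run_id, *rows):
    """rows: (peptide, count, owners) triples."""
    return [
        PeptideEvidence(run_id, pep, count, frozenset(owners))
        for pep, count, owners in rows
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
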