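import pytest
from hypothesis import settings

from ddsm import LabeledSequenceSet, load_matrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

#: The nine worked-example motifs with their published main-motif assignment.
WORKED_MOTIFS = ["LLK", "IMK", "VMK", "GGP", "RI", "RV", "RF", "RA", "PP"]
WORKED_MAIN_OF = {
    "LLK": "LLK",
    "IMK": "LLK",
    "VMK": "LLK",
    "GGP": "GGP",
    "RI": "RI",
    "RV": "RI",
    "RF": "RI",
    "RA": "RV",
    "PP": "PP",
}


@pytest.fixture(scope="session")
def blosum62():
    return load_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def all_matrices():
    from ddsm import bundled_matrix_names

    return {name: load_matrix(name) for name in bundled_matrix_names()}


@pytest.fixture
def two_family_set():
    return LabeledSequenceSet.from_records(
        [
            ("a1", "MKLVA", "F1"),
            ("a2", "MKLVC", "F1"),
            ("b1", "GGPQR", "F2"),
            ("b2", "GGPQS", "F2"),
        ]
    )
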