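import numpy as np
import pytest

from selexpipe import LibraryDesign

# Printed N40 selection library: 18-nt constant flanks around the random core.
FLANK5 = "ATCCAGAGTGACGCAGCA"
FLANK3 = "TGGACACGGTGGCTTAGT"
REVERSE_PRIMER = "ACTAAGCCACCGTGTCCA"

# The three top-ranked candidate inserts taken forward to binding assays.
SP_SEQUENCES = {
    "SP1": "CACTCTCACCTTCCTGTCACTCCTTTTTTCACTCTCACTC",
    "SP2": "CACTCACTCTTTCCCTTATCTGCTCACTCTTCATTCACTC",
    "SP3": "CACCGTCCTTTTCTAGCATCTCTGTCACTCTTTCTCACTC",
}

# Final-round candidate report: read counts and insert lengths of the 15
# sequences exceeding 25 reads.
TABLE4_COUNTS = [252, 61, 53, 48, 41, 37, 37, 37, 33, 30, 29, 28, 28, 28, 26]
TABLE4_LENGTHS = [40, 40, 40, 39, 40, 40, 40, 40, 40, 40, 40, 40, 39, 40, 40]


@pytest.fixture
def design() -> LibraryDesign:
    return LibraryDesign()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_bases(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
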