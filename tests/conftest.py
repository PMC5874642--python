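import numpy as np
import pytest

from epiprof import tables
from epiprof.seqio import ProteinRecord, read_protein

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def mica() -> ProteinRecord:
    """The reconstructed MIC-A precursor shipped with the package."""
    return read_protein(tables.reference_mica_path())[0]


@pytest.fixture(scope="session")
def kolaskar_values() -> dict:
    return tables.kolaskar_scale()


@pytest.fixture(scope="session")
def kd_values() -> dict:
    return tables.kd_scale()


def random_sequences(n: int, min_len: int, max_len: int, seed: int):
    """Deterministic batch of random protein strings for oracle comparisons."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        L = int(rng.integers(min_len, max_len + 1))
        out.append("".join(rng.choice(list(AA), size=L)))
    return out
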