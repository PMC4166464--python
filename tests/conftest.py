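import numpy as np
import pytest

from crypticdelim.io_formats import Alignment
from crypticdelim.synthetic_data import SimConfig, simulate_dataset


def make_alignment(rows: dict[str, str], locus: str = "locus") -> Alignment:
    """Build an Alignment from an ordered {specimen_id: sequence} dict."""
    return Alignment(locus, list(rows),
                     np.array([list(s) for s in rows.values()], dtype="<U1"))


def random_alignment(rng: np.random.Generator, n_seqs: int, n_cols: int,
                     chars: str = "ACGT-N?", locus: str = "rand",
                     weights: list[float] | None = None) -> Alignment:
    """Random alignment over the given character pool (seeded)."""
    pool = np.array(list(chars), dtype="<U1")
    if weights is None:
        # bias toward bases so gaps/missing stay sparse
        weights = [4.0 if c in "ACGT" else 0.5 for c in chars]
    p = np.array(weights) / np.sum(weights)
    states = rng.choice(pool, size=(n_seqs, n_cols), p=p)
    ids = [f"s{i:02d}" for i in range(n_seqs)]
    return Alignment(locus, ids, states)


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic dataset: 6 species x 8 specimens x 3 loci."""
    return simulate_dataset(SimConfig(seed=1234))
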