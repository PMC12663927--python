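import numpy as np
import pytest

from rubiscope.seqspace import AMINO_ACIDS, AlignedSeqSet
from rubiscope.synthetic import CausalSite, SimConfig, simulate_dataset


def random_alignment(
    n: int, length: int, seed: int, gap_frac: float = 0.0, n_states: int = 20
) -> AlignedSeqSet:
    """An i.i.d. random alignment (no phylogenetic structure)."""
    rng = np.random.default_rng(seed)
    chars = np.array(list(AMINO_ACIDS[:n_states]))
    mat = rng.choice(chars, size=(n, length))
    if gap_frac > 0:
        mat[rng.random((n, length)) < gap_frac] = "-"
    rows = ["".join(r) for r in mat]
    return AlignedSeqSet(ids=[f"s{i:03d}" for i in range(n)], rows=rows)


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic survey shared by read-only tests."""
    cfg = SimConfig(n_leaves=60, length=120, seed=3, frac_characterized=0.6)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_dataset():
    """Survey with a strong planted causal position and no trait drift."""
    cfg = SimConfig(
        n_leaves=60,
        length=120,
        seed=5,
        sigma2=0.0,
        sigma_obs=0.1,
        frac_characterized=0.6,
        causal_sites=[CausalSite(position=50, delta=1.0)],
    )
    return simulate_dataset(cfg)
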