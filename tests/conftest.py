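import numpy as np
import pytest

from compqc.seqio import Alignment, PhyloTree


@pytest.fixture
def toy_alignment() -> Alignment:
    return Alignment(["A", "B"], ["AAAA", "AAAC"], name="toy")


@pytest.fixture
def quartet_tree() -> PhyloTree:
    return PhyloTree.from_newick("((A:0.12,B:0.34):0.05,(C:0.2,D:0.4):0.07);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def random_pi(rng: np.random.Generator, concentration: float = 5.0) -> np.ndarray:
    pi = rng.dirichlet(np.full(20, concentration))
    pi = np.clip(pi, 1e-4, None)
    return pi / pi.sum()
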