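import numpy as np
import pytest

from lmmacnet.network import LMMACNetwork
from lmmacnet.pairs import CompetingPair, HypergeomInputs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_pair(gene: str, lncrna: str, mirnas: set[str], *, M: int = 20,
              p_hyper: float = 1e-4, significant: bool = True,
              pcc: float | None = None) -> CompetingPair:
    """Minimal valid CompetingPair for construction-level tests."""
    x = len(mirnas)
    return CompetingPair(
        gene_id=gene, lncrna_id=lncrna, shared_mirnas=frozenset(mirnas),
        hyper=HypergeomInputs(M=M, K=x, N=x, x=x), p_hyper=p_hyper,
        pcc=pcc, significant=significant)


def net_from_triplets(triplets) -> LMMACNetwork:
    """Build an LMMACNetwork directly from raw (gene, miRNA, lncRNA) records."""
    triplets = frozenset(tuple(t) for t in triplets)
    return LMMACNetwork(
        genes=frozenset(t[0] for t in triplets),
        mirnas=frozenset(t[1] for t in triplets),
        lncrnas=frozenset(t[2] for t in triplets),
        gm_edges=frozenset((t[0], t[1]) for t in triplets),
        ml_edges=frozenset((t[1], t[2]) for t in triplets),
        triplets=triplets)
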