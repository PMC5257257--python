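import numpy as np
import pytest

from gtscreen.annotation import GeneModel
from gtscreen.mapping import InsertionSite


@pytest.fixture
def plus_gene() -> GeneModel:
    """A 3-exon gene on the + strand: exons 100-200, 400-500, 800-900."""
    return GeneModel("PLUS1", "chr1", "+", 100, 900,
                     ((100, 200), (400, 500), (800, 900)))


@pytest.fixture
def minus_gene() -> GeneModel:
    """A 3-exon gene on the - strand: span 2000-2900."""
    return GeneModel("MINUS1", "chr1", "-", 2000, 2900,
                     ((2000, 2100), (2400, 2500), (2800, 2900)))


@pytest.fixture
def two_genes(plus_gene, minus_gene) -> list[GeneModel]:
    return [plus_gene, minus_gene]


def random_sites(rng: np.random.Generator, n: int, span: int = 1000,
                 chroms=("chr1", "chr2")) -> list[InsertionSite]:
    """Dense random sites for collapse stress tests (duplicates removed)."""
    seen = set()
    out = []
    for _ in range(n):
        key = (str(rng.choice(chroms)), int(rng.integers(0, span)),
               str(rng.choice(["+", "-"])))
        if key not in seen:
            seen.add(key)
            out.append(InsertionSite(*key, int(rng.integers(1, 6))))
    return out
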