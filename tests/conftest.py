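import numpy as np
import pandas as pd
import pytest

from basalkit.ancestry_alleles import BasnAlleleSet, assign_blocks
from basalkit.io_formats import HaplotypeMatrix, PopulationPanel, SiteInfo


def make_matrix(haps, positions=None, chrom="1", ancestral="A", sample_prefix="S"):
    """HaplotypeMatrix from a raw 0/1 array (rows = haplotypes)."""
    haps = np.asarray(haps, dtype=np.int8)
    n, m = haps.shape
    if positions is None:
        positions = 1000 * (1 + np.arange(m))
    sites = [
        SiteInfo(
            chrom=chrom,
            pos=int(positions[j]),
            ref_allele="A",
            alt_allele="G",
            ancestral_allele=ancestral,
            site_id=f"s{j}",
        )
        for j in range(m)
    ]
    ids = [f"{sample_prefix}{i}" for i in range(n // 2)]
    return HaplotypeMatrix(sites, haps, ids)


def make_panel(pops_sizes, categories):
    """Panel for samples named <pop>_<i> matching synthetic_data conventions."""
    s2p = {}
    for pop, n in pops_sizes.items():
        for i in range(n):
            s2p[f"{pop}_{i}"] = pop
    return PopulationPanel(s2p, categories)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def block_alleles():
    """100 bASN alleles, one per 600-kb step -> all singleton blocks."""
    t = pd.DataFrame(
        {
            "site_id": [f"b{i}" for i in range(100)],
            "chrom": "1",
            "pos": np.arange(100) * 600_000 + 1,
            "allele": "G",
            "stage": "seed",
        }
    )
    return assign_blocks(BasnAlleleSet(t))
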