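"""Pigmentation-allele analyses on synthetic data: DPA-count polygenic score
vs ancestry, putative-DPA classification, the African-sharing contingency
test, and an AF-block screen around a target variant.

Finding: when DPA frequency rises linearly with an individual's basal
ancestry fraction, the unweighted DPA count tracks ancestry (r > 0.5 here);
population-specific pigmentary alleles constructed to be African-shared give
an odds ratio < 1 in the sharing test.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from basalkit import pigmentation as pig
from basalkit.io_formats import PopulationPanel, write_tsv

from basalkit.io_formats import HaplotypeMatrix, SiteInfo

OUT = Path("results/analysis")
rng = np.random.default_rng(20260926)

# DPA PRS vs ancestry: 200 individuals, 24 DPA loci, per-haplotype DPA
# probability linear in the ancestry fraction
n, n_sites = 200, 24
ancestry = rng.uniform(0, 1, n)
p = 0.1 + 0.6 * ancestry
haps = (rng.random((2 * n, n_sites)) < np.repeat(p, 2)[:, None]).astype(np.int8)
sites = [
    SiteInfo("1", 10_000 * (j + 1), "A", "G", "A", f"dpa{j}") for j in range(n_sites)
]
matrix = HaplotypeMatrix(sites, haps, [f"ind{i}" for i in range(n)])
table = pig.PigmentVariantTable(
    pd.DataFrame(
        {"site_id": [f"dpa{j}" for j in range(n_sites)], "effect_allele": "G",
         "direction": "DPA", "group": "AFR", "gene": "demo"}
    )
)
prs = pig.prs_dpa(matrix, table, group="AFR")
prs["ancestry_fraction"] = ancestry
write_tsv(prs, OUT / "dpa_prs.tsv")
r = np.corrcoef(prs["prs"], ancestry)[0, 1]
print(f"DPA-count PRS vs ancestry fraction: r = {r:.2f} over {n} individuals")

# putative-DPA classification + African sharing
n_var = 200
af = pd.DataFrame(
    {"ADM": rng.uniform(0, 0.5, n_var), "PNG": rng.uniform(0, 0.5, n_var),
     "EUR": rng.uniform(0, 0.3, n_var), "EAS": rng.uniform(0, 0.3, n_var)}
)
specific = rng.random(n_var) < 0.25
af.loc[specific, ["EUR", "EAS"]] = 0.0
flags = pig.classify_putative_dpa(af, ["ADM", "PNG"], ["EUR", "EAS"])
write_tsv(flags, OUT / "dpa_classification.tsv")
print(f"{int(flags['putative_dpa'].sum())} putative DPAs, "
      f"{int(flags['population_specific'].sum())} population-specific")

# sharing test: pigmentary specific alleles mostly African-shared by construction
pigmentary = rng.random(n_var) < 0.3
shared = np.where(pigmentary, rng.random(n_var) < 0.8, rng.random(n_var) < 0.95)
spec = flags["population_specific"].to_numpy()
res = pig.sharing_contingency(
    int((spec & pigmentary & shared).sum()),
    int((spec & pigmentary & ~shared).sum()),
    int((spec & ~pigmentary & shared).sum()),
    int((spec & ~pigmentary & ~shared).sum()),
)
print(f"African-sharing contingency: OR = {res['odds_ratio']:.2f}, "
      f"p = {res['p_value']:.3g}")

# AF-block screen around a planted 150-kb haplotype at AF 0.8
span, m_sites = 400_000, 400
pos = np.sort(rng.choice(np.arange(1, span), m_sites, replace=False))
freq = rng.uniform(0.05, 0.3, m_sites)
inside = (pos >= 60_000) & (pos < 210_000)
freq[inside] = 0.8
bh = (rng.random((100, m_sites)) < freq).astype(np.int8)
bm = HaplotypeMatrix(
    [SiteInfo("1", int(pp), "A", "G", "A", f"s{j}") for j, pp in enumerate(pos)],
    bh, [f"x{i}" for i in range(50)],
)
panel = PopulationPanel({f"x{i}": "P" for i in range(50)}, {"P": "representative_TIA"})
target = f"s{int(np.flatnonzero(inside)[inside.sum() // 2])}"
blocks = pig.af_block_scan(bm, panel, ["P"], target, f=0.8)
union = pig.union_blocks(blocks)
write_tsv(blocks, OUT / "af_blocks.tsv")
print(f"AF block around {target}: {union} (planted span 60000-210000)")
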