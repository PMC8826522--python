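"""Pigmentation-allele scoring: DPA/LPA handling, the DPA-count polygenic
score, putative-DPA classification with the African-sharing contingency
test, and the allele-frequency block screen used to delimit candidate
haplotype regions.

DPA/LPA are the dark- and light-pigmentation alleles of a pigmentation-
associated variant; at each scored site they are the two opposite alleles.
The unweighted polygenic score of a sample is simply its diploid count of
DPA alleles over the scored loci.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import HaplotypeMatrix, PopulationPanel


@dataclasses.dataclass
class PigmentVariantTable:
    """Effect-allele table: site_id, effect_allele, direction (DPA/LPA), group, gene."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"site_id", "effect_allele", "direction"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"pigment table needs columns {sorted(required)}")
        bad = set(self.table["direction"]) - {"DPA", "LPA"}
        if bad:
            raise ValueError(f"direction must be DPA or LPA, got {sorted(bad)}")
        if self.table.duplicated(["site_id", "effect_allele"]).any():
            raise ValueError("duplicate (site, allele) rows in pigment table")

    def dpa_sites(self, group: str | None = None) -> pd.DataFrame:
        t = self.table[self.table["direction"] == "DPA"]
        if group is not None and "group" in t.columns:
            t = t[t["group"] == group]
        return t

    @classmethod
    def from_tsv(cls, path) -> "PigmentVariantTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"site_id": str}))


def prs_dpa(
    geno: HaplotypeMatrix, table: PigmentVariantTable, group: str | None = None
) -> pd.DataFrame:
    """Unweighted DPA-count polygenic score per sample.

    Counts 0/1/2 copies of the DPA effect allele per scored site and sums.
    Sites absent from the matrix contribute 0 and are reported in
    ``n_missing_sites`` (same for every sample, as modern phased data carry
    no per-sample missingness).
    """
    dpa = table.dpa_sites(group)
    counts = np.zeros(geno.n_samples, dtype=int)
    n_scored = 0
    n_missing = 0
    known = {s.site_id: i for i, s in enumerate(geno.sites)}
    for row in dpa.itertuples(index=False):
        j = known.get(row.site_id)
        if j is None:
            n_missing += 1
            continue
        site = geno.sites[j]
        derived_count = geno.haplotypes[0::2, j].astype(int) + geno.haplotypes[1::2, j]
        if row.effect_allele == site.derived_allele:
            counts += derived_count
        else:
            counts += 2 - derived_count
        n_scored += 1
    return pd.DataFrame(
        {
            "sample": geno.sample_ids,
            "prs": counts,
            "n_scored_sites": n_scored,
            "n_missing_sites": n_missing,
        }
    )


def classify_putative_dpa(
    af: pd.DataFrame, tia_pops: Sequence[str], nonind_eur_pops: Sequence[str]
) -> pd.DataFrame:
    """Classify alleles by TIA-vs-nonindigenous-Eurasian frequency contrast.

    ``putative_dpa``: maximum AF over the representative TIA populations
    exceeds the maximum over the nonindigenous Eurasians.
    ``population_specific``: present (AF > 0) in at least one TIA population
    and absent (AF = 0) from every nonindigenous Eurasian population.
    """
    out = af.copy()
    tia_max = af[list(tia_pops)].max(axis=1)
    eur_max = af[list(nonind_eur_pops)].max(axis=1)
    out["putative_dpa"] = tia_max > eur_max
    out["population_specific"] = (tia_max > 0) & (eur_max == 0)
    return out


def _conditional_mle_or(table: np.ndarray) -> float:
    """Conditional maximum-likelihood odds ratio of a 2x2 table.

    Maximizes the Fisher noncentral hypergeometric likelihood of the [0, 0]
    cell given the margins (the odds ratio R's fisher.test reports).
    """
    a, b = table[0]
    c, d = table[1]
    M = a + b + c + d
    n = a + b  # row-1 total
    N = a + c  # col-1 total
    lo = max(0, n + N - M)
    hi = min(n, N)
    if a == lo:
        return 0.0
    if a == hi:
        return np.inf

    def neg_ll(log_psi: float) -> float:
        return -stats.nchypergeom_fisher.logpmf(a, M, N, n, np.exp(log_psi))

    res = optimize.minimize_scalar(neg_ll, bounds=(-50, 50), method="bounded")
    return float(np.exp(res.x))


def sharing_contingency(
    pigmentary_specific_shared: int,
    pigmentary_specific_unshared: int,
    other_specific_shared: int,
    other_specific_unshared: int,
) -> dict:
    """African-sharing contingency test for population-specific alleles.

    Rows: pigmentary vs non-pigmentary population-specific alleles; columns:
    present vs absent in Africans.  Returns the table, the conditional-MLE
    odds ratio and the two-sided Fisher exact p.
    """
    table = np.array(
        [
            [pigmentary_specific_shared, pigmentary_specific_unshared],
            [other_specific_shared, other_specific_unshared],
        ],
        dtype=np.int64,
    )
    if (table < 0).any():
        raise ValueError("contingency counts must be non-negative")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "table": table,
        "odds_ratio": _conditional_mle_or(table),
        "p_value": float(p),
    }


def af_block_scan(
    geno: HaplotypeMatrix,
    panel: PopulationPanel,
    populations: Sequence[str],
    target_site: str,
    f: float,
    window_bp: int = 50_000,
    min_alleles: int = 5,
    tol: float = 0.05,
) -> pd.DataFrame:
    """Allele-frequency block around a target variant.

    Per population: 1) count alleles at frequency f (|AF - f| <= tol) in
    non-overlapping ``window_bp`` windows, 2) keep windows with at least
    ``min_alleles`` such alleles, 3) merge adjacent kept windows and retain
    the merged block containing the target.  The returned table is the union
    of the per-population blocks (one row per population with a qualifying
    block; empty if the target falls in no qualifying window anywhere).
    """
    j = geno.site_index(target_site)
    target = geno.sites[j]
    pos = geno.positions
    same_chrom = np.array([s.chrom == target.chrom for s in geno.sites])
    rows_out = []
    for pop in populations:
        rows = geno.sample_haplotype_rows(panel.samples_of(pop))
        af = geno.derived_freq(rows)
        near_f = same_chrom & (np.abs(af - f) <= tol)
        win = (pos - 1) // window_bp
        kept = {
            int(w)
            for w in np.unique(win[near_f])
            if (near_f & (win == w)).sum() >= min_alleles
        }
        target_win = int((target.pos - 1) // window_bp)
        if target_win not in kept:
            continue
        lo = target_win
        while lo - 1 in kept:
            lo -= 1
        hi = target_win
        while hi + 1 in kept:
            hi += 1
        rows_out.append(
            {
                "population": pop,
                "chrom": target.chrom,
                "start": lo * window_bp,
                "end": (hi + 1) * window_bp,
                "n_alleles": int(near_f[(win >= lo) & (win <= hi)].sum()),
            }
        )
    return pd.DataFrame(
        rows_out, columns=["population", "chrom", "start", "end", "n_alleles"]
    )


def union_blocks(blocks: pd.DataFrame) -> tuple[str, int, int] | None:
    """Union of per-population AF blocks (they all contain the target)."""
    if len(blocks) == 0:
        return None
    return (
        blocks["chrom"].iloc[0],
        int(blocks["start"].min()),
        int(blocks["end"].max()),
    )


def subsample_for_network(
    panel: PopulationPanel,
    samples: Sequence[str],
    carriers: Sequence[str],
    cap_frac: float = 0.5,
    min_pop_size: int = 50,
    seed: int = 0,
) -> list[str]:
    """Downsample large populations for haplotype-network construction.

    Populations with <= ``min_pop_size`` samples are kept whole; larger ones
    are downsampled to ``cap_frac`` of their size, always retaining every
    carrier of the target allele (the cap may be exceeded by carriers).
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    carriers = set(carriers)
    by_pop: dict[str, list[str]] = {}
    for s in samples:
        by_pop.setdefault(panel.sample_to_pop[s], []).append(s)
    kept: list[str] = []
    for pop in sorted(by_pop):
        members = by_pop[pop]
        if len(members) <= min_pop_size:
            kept.extend(members)
            continue
        target_n = int(round(cap_frac * len(members)))
        pop_carriers = [s for s in members if s in carriers]
        others = [s for s in members if s not in carriers]
        n_fill = max(target_n - len(pop_carriers), 0)
        fill = list(rng.choice(others, size=min(n_fill, len(others)), replace=False))
        kept.extend(pop_carriers + sorted(fill))
    return kept
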