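"""Weir–Cockerham F_ST machinery, window scans, gene outliers and the NJ tree.

Allele counts enter the estimator at the haplotype level (the data are
phased), i.e. as haploid samples: the heterozygosity component of the 1984
variance decomposition vanishes and the remaining between/within components
``a`` and ``b`` carry the signal.  Genome-wide values are the ratio of sums
Sigma a / Sigma (a + b + c) over sites ("weighted" combination), the standard
recommendation for this estimator.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import HaplotypeMatrix, PopulationPanel


@dataclasses.dataclass
class FstComponents:
    """Per-site variance components for one population set."""

    site_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    a: np.ndarray  # between-population component
    bc: np.ndarray  # within-population remainder (b + c)

    @property
    def per_site(self) -> np.ndarray:
        """Per-SNP F_ST a / (a + b + c); NaN where the denominator is 0."""
        denom = self.a + self.bc
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom != 0, self.a / denom, np.nan)


def _wc_components(counts: np.ndarray, sizes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weir–Cockerham (1984) components for haploid samples, vectorized.

    ``counts``: (n_sites, r) derived-allele counts; ``sizes``: (r,) haplotype
    sample sizes.  Returns (a, b+c) per site; monomorphic sites give (0, 0).
    """
    r = counts.shape[1]
    if r < 2:
        raise ValueError("need at least two populations")
    n_i = sizes.astype(float)
    nbar = n_i.mean()
    n_total = n_i.sum()
    nc = (n_total - (n_i**2).sum() / n_total) / (r - 1)
    p_i = counts / n_i  # (sites, r)
    pbar = counts.sum(axis=1) / n_total
    s2 = (n_i * (p_i - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
    # haploid: hbar = 0, c = 0
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2)
    mono = (pbar == 0) | (pbar == 1)
    a = np.where(mono, 0.0, a)
    b = np.where(mono, 0.0, b)
    return a, b


def fst_per_snp(
    geno: HaplotypeMatrix, panel: PopulationPanel, pops: Sequence[str]
) -> FstComponents:
    """Per-SNP Weir–Cockerham variance components for ``r = len(pops)`` populations."""
    counts = np.empty((geno.n_sites, len(pops)), dtype=float)
    sizes = np.empty(len(pops), dtype=float)
    for k, pop in enumerate(pops):
        samples = panel.samples_of(pop)
        if not samples:
            raise KeyError(f"population {pop!r} has no samples in panel")
        rows = geno.sample_haplotype_rows(samples)
        if len(rows) < 2:
            raise ValueError(f"population {pop!r} needs >= 2 haplotypes")
        counts[:, k] = geno.haplotypes[rows].sum(axis=0)
        sizes[k] = len(rows)
    a, b = _wc_components(counts, sizes)
    return FstComponents(
        site_ids=[s.site_id for s in geno.sites],
        chrom=np.array([s.chrom for s in geno.sites]),
        pos=geno.positions,
        a=a,
        bc=b,
    )


def fst_from_counts(counts: np.ndarray, sizes: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Variance components straight from (n_sites, r) derived counts and sizes."""
    return _wc_components(np.asarray(counts, dtype=float), np.asarray(sizes, dtype=float))


def components_ratio(a: np.ndarray, bc: np.ndarray) -> np.ndarray:
    """Per-site F_ST a / (a + b + c); NaN where the denominator vanishes."""
    denom = np.asarray(a) + np.asarray(bc)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom != 0, a / denom, np.nan)


def pairwise_per_site_fst(counts_a, size_a, counts_b, size_b) -> np.ndarray:
    """Convenience: per-site pairwise F_ST from two populations' derived counts."""
    a, bc = fst_from_counts(np.column_stack([counts_a, counts_b]), [size_a, size_b])
    return components_ratio(a, bc)


def fst_weighted(components: FstComponents) -> float:
    """Genome-wide ratio-of-sums F_ST."""
    denom = (components.a + components.bc).sum()
    if denom == 0:
        raise ValueError("all sites monomorphic; weighted F_ST undefined")
    return float(components.a.sum() / denom)


def fst_windows(
    components: FstComponents, window_bp: int = 10_000, step_bp: int = 1_000
) -> pd.DataFrame:
    """Sliding-window ratio-of-sums F_ST.

    Windows are anchored at multiples of ``step_bp`` from position 0 within
    each chromosome; a site belongs to every window whose half-open span
    [start+1, start+window_bp] contains its position.  Empty windows are
    omitted.
    """
    rows = []
    for chrom in dict.fromkeys(components.chrom.tolist()):
        mask = components.chrom == chrom
        pos = components.pos[mask]
        a = components.a[mask]
        bc = components.bc[mask]
        order = np.argsort(pos)
        pos, a, bc = pos[order], a[order], bc[order]
        first_start = ((pos.min() - window_bp) // step_bp) * step_bp
        first_start = max(first_start, 0)
        last_start = ((pos.max() - 1) // step_bp) * step_bp
        for start in range(int(first_start), int(last_start) + 1, step_bp):
            lo = np.searchsorted(pos, start + 1)
            hi = np.searchsorted(pos, start + window_bp, side="right")
            if hi <= lo:
                continue
            denom = a[lo:hi].sum() + bc[lo:hi].sum()
            fst = a[lo:hi].sum() / denom if denom != 0 else np.nan
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + window_bp,
                    "n_snps": hi - lo,
                    "fst": fst,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "fst"])


def gene_fst_outliers(
    windows: pd.DataFrame, genes: pd.DataFrame, z_threshold: float = 1.96
) -> pd.DataFrame:
    """Per-gene top-window F_ST, sqrt-normalized z-scores and outlier flags.

    A gene's value is the maximum F_ST over windows overlapping it
    (1-based inclusive gene intervals vs 0-based half-open windows); negative
    values are truncated at 0 before the square-root transform, and z-scores
    are taken across genes.
    """
    records = []
    for g in genes.itertuples(index=False):
        mask = (
            (windows["chrom"] == g.chrom)
            & (windows["start"] + 1 <= g.end)
            & (windows["end"] >= g.start)
        )
        sub = windows.loc[mask, "fst"].dropna()
        records.append(
            {"gene": g.gene, "fst": float(sub.max()) if len(sub) else np.nan}
        )
    table = pd.DataFrame(records).dropna(subset=["fst"]).reset_index(drop=True)
    table["sqrt_fst"] = np.sqrt(np.clip(table["fst"], 0.0, None))
    sd = table["sqrt_fst"].std(ddof=1)
    if sd == 0 or np.isnan(sd):
        table["z"] = 0.0
    else:
        table["z"] = (table["sqrt_fst"] - table["sqrt_fst"].mean()) / sd
    table["outlier"] = table["z"] > z_threshold
    return table


def pairwise_fst_matrix(
    geno: HaplotypeMatrix, panel: PopulationPanel, pops: Sequence[str]
) -> pd.DataFrame:
    """Symmetric matrix of pairwise weighted F_ST (zero diagonal, clipped at 0)."""
    k = len(pops)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            comp = fst_per_snp(geno, panel, [pops[i], pops[j]])
            d[i, j] = d[j, i] = max(fst_weighted(comp), 0.0)
    return pd.DataFrame(d, index=list(pops), columns=list(pops))


def nj_tree(
    distances: pd.DataFrame, outgroup: str | None = None
) -> str:
    """Neighbor-joining tree from a distance matrix, as a Newick string.

    Rooted on ``outgroup`` when given; negative branch lengths are clamped
    to zero.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj as _nj

    labels = list(distances.index)
    dm = DistanceMatrix(distances.to_numpy(dtype=float), labels)
    tree = _nj(dm)
    if outgroup is not None:
        if outgroup not in labels:
            raise KeyError(f"outgroup {outgroup!r} not among taxa")
        tree = tree.root_by_outgroup([outgroup])
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()
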