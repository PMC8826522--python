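"""EHH/iHS, locus-specific branch length (LSBL), and the composite F_CS scan.

Per SNP the scan combines two signals: the integrated haplotype score
iHS = ln(iHH_ancestral / iHH_derived), where iHH is the area under the
extended-haplotype-homozygosity curve against physical distance, truncated
where EHH drops below 0.05; and the locus-specific branch length
LSBL = (d_FR + d_FO - d_RO) / 2 from the three pairwise per-SNP F_ST values
of focal, reference and outgroup populations.  Each statistic is converted
to a genome-wide empirical p (|iHS| two-sided, LSBL upper tail) and combined
as F_CS = -log10 p_iHS - log10 p_LSBL.  Outlier SNPs are the top 5% of F_CS;
putatively selected regions are non-overlapping 100-kb windows (>= 10 SNPs)
whose outlier-SNP proportion ranks in the top 5% within their SNP-count
quartile bin.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import HaplotypeMatrix


# ---------------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------------

def ehh(
    haps: np.ndarray, core_index: int, direction: str = "right"
) -> tuple[np.ndarray, np.ndarray]:
    """EHH curve for one haplotype class from a core site outward.

    ``haps`` holds the haplotypes of a single core-allele class (rows) over
    ordered sites (columns).  Returns (site_indices, ehh_values) for the
    sites from the core to the chosen edge, starting with EHH(core) = 1.
    EHH at site x is the fraction of haplotype pairs identical over every
    site between the core and x inclusive.
    """
    n, m = haps.shape
    if n < 2:
        raise ValueError("need >= 2 haplotypes in the core class")
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    step = 1 if direction == "right" else -1
    idx = list(range(core_index, m if step == 1 else -1, step))
    groups = np.zeros(n, dtype=np.int64)
    total_pairs = n * (n - 1) / 2
    values = []
    for j in idx:
        key = groups * 2 + haps[:, j]
        _, groups = np.unique(key, return_inverse=True)
        counts = np.bincount(groups)
        same = (counts * (counts - 1) / 2).sum()
        values.append(same / total_pairs)
    return np.array(idx), np.array(values)


def _numba_ihs_kernel():
    """Build (once) the jitted per-site iHH walker."""
    import numba

    @numba.njit
    def iHH_one_side(haps, pos, core, members, step, trunc, max_gap):
        # returns (iHH, ok_flag); ok=False when the chromosome edge is hit
        # with EHH still above trunc, or a gap exceeds max_gap
        n = members.shape[0]
        m = haps.shape[1]
        groups = np.zeros(n, dtype=np.int64)
        remap = np.full(2 * n, -1, dtype=np.int64)  # key -> new compact label
        total_pairs = n * (n - 1) / 2.0
        prev_ehh = 1.0
        prev_pos = pos[core]
        area = 0.0
        j = core
        while True:
            j += step
            if j < 0 or j >= m:
                return area, False
            gap = pos[j] - prev_pos if step == 1 else prev_pos - pos[j]
            if gap > max_gap:
                return area, False
            # refine partition by allele at site j: key = old_group*2 + allele
            n_groups = 0
            for i in range(n):
                k = groups[i] * 2 + haps[members[i], j]
                if remap[k] == -1:
                    remap[k] = n_groups
                    n_groups += 1
                groups[i] = remap[k]
            same = 0.0
            counts = np.zeros(n_groups, dtype=np.int64)
            for i in range(n):
                counts[groups[i]] += 1
            for g in range(n_groups):
                same += counts[g] * (counts[g] - 1) / 2.0
                remap[2 * g] = -1
                remap[2 * g + 1] = -1
            cur_ehh = same / total_pairs
            area += 0.5 * (prev_ehh + cur_ehh) * gap
            if cur_ehh < trunc or cur_ehh == 0.0:
                return area, True
            prev_ehh = cur_ehh
            prev_pos = pos[j]

    @numba.njit
    def ihs_all(haps, pos, maf_min, trunc, max_gap):
        m = haps.shape[1]
        n = haps.shape[0]
        out = np.full(m, np.nan)
        daf = np.empty(m)
        for j in range(m):
            s = 0
            for i in range(n):
                s += haps[i, j]
            daf[j] = s / n
        der = np.empty(n, dtype=np.int64)
        anc = np.empty(n, dtype=np.int64)
        for j in range(m):
            p = daf[j]
            if min(p, 1 - p) < maf_min:
                continue
            a = 0
            b = 0
            for i in range(n):
                if haps[i, j] == 1:
                    der[a] = i
                    a += 1
                else:
                    anc[b] = i
                    b += 1
            if a < 2 or b < 2:
                continue
            dr, ok1 = iHH_one_side(haps, pos, j, der[:a], 1, trunc, max_gap)
            dl, ok2 = iHH_one_side(haps, pos, j, der[:a], -1, trunc, max_gap)
            ar, ok3 = iHH_one_side(haps, pos, j, anc[:b], 1, trunc, max_gap)
            al, ok4 = iHH_one_side(haps, pos, j, anc[:b], -1, trunc, max_gap)
            if not (ok1 and ok2 and ok3 and ok4):
                continue
            ihh_d = dr + dl
            ihh_a = ar + al
            if ihh_d <= 0.0 or ihh_a <= 0.0:
                continue
            out[j] = np.log(ihh_a / ihh_d)
        return out, daf

    return ihs_all


_IHS_ALL = None


def ihs(
    geno: HaplotypeMatrix,
    rows: np.ndarray | None = None,
    maf_min: float = 0.05,
    truncation_ehh: float = 0.05,
    max_gap_bp: int = 200_000,
    standardize_bins: int = 20,
) -> pd.DataFrame:
    """Standardized iHS per site for one population.

    Unstandardized scores are standardized to mean 0 / SD 1 within
    derived-allele-frequency bins (``standardize_bins`` equal-width bins on
    [0, 1]).  Sites failing the MAF filter, lacking polarization, hitting a
    chromosome edge before EHH truncation, or spanning a gap larger than
    ``max_gap_bp`` are returned as NaN.
    """
    global _IHS_ALL
    if _IHS_ALL is None:
        _IHS_ALL = _numba_ihs_kernel()
    h = geno.haplotypes if rows is None else geno.haplotypes[rows]
    h = np.ascontiguousarray(h, dtype=np.int8)
    pos = geno.positions.astype(np.float64)
    raw, daf = _IHS_ALL(h, pos, maf_min, truncation_ehh, float(max_gap_bp))
    raw = np.asarray(raw)
    daf = np.asarray(daf)
    raw[~geno.polarized_mask] = np.nan

    std = np.full_like(raw, np.nan)
    bins = np.clip((daf * standardize_bins).astype(int), 0, standardize_bins - 1)
    for b in range(standardize_bins):
        mask = (bins == b) & np.isfinite(raw)
        if mask.sum() >= 2:
            mu = raw[mask].mean()
            sd = raw[mask].std(ddof=0)
            if sd > 0:
                std[mask] = (raw[mask] - mu) / sd
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in geno.sites],
            "pos": geno.positions,
            "daf": daf,
            "ihs_raw": raw,
            "ihs": std,
        }
    )


# ---------------------------------------------------------------------------
# LSBL
# ---------------------------------------------------------------------------

def lsbl(
    fst_focal_ref: np.ndarray | float,
    fst_focal_out: np.ndarray | float,
    fst_ref_out: np.ndarray | float,
) -> np.ndarray | float:
    """Focal-population branch length from three pairwise per-SNP F_ST values.

    Negative F_ST inputs are truncated at 0 before the three-point formula.
    """
    d_fr = np.clip(fst_focal_ref, 0.0, None)
    d_fo = np.clip(fst_focal_out, 0.0, None)
    d_ro = np.clip(fst_ref_out, 0.0, None)
    return (d_fr + d_fo - d_ro) / 2.0


# ---------------------------------------------------------------------------
# empirical p and F_CS
# ---------------------------------------------------------------------------

def empirical_p(values: np.ndarray, side: str = "upper") -> np.ndarray:
    """Genome-wide empirical p per site: rank of the value / n, rank 1 = most extreme.

    ``side='upper'`` ranks large values as extreme; ``side='two'`` ranks by
    absolute value.  Ties share the smallest rank of their group; NaNs stay NaN.
    """
    v = np.asarray(values, dtype=float)
    if side == "two":
        v = np.abs(v)
    elif side != "upper":
        raise ValueError("side must be 'upper' or 'two'")
    out = np.full(v.shape, np.nan)
    ok = np.isfinite(v)
    n = int(ok.sum())
    if n == 0:
        return out
    ranks = rankdata(-v[ok], method="min")
    out[ok] = ranks / n
    return out


def fcs(p_ihs: np.ndarray | float, p_lsbl: np.ndarray | float) -> np.ndarray | float:
    """Composite score -log10(p_iHS) - log10(p_LSBL); NaN propagates."""
    return -np.log10(p_ihs) - np.log10(p_lsbl)


def _top_frac_flags(values: np.ndarray, top_frac: float) -> np.ndarray:
    """Flag the top fraction of values, ties at the threshold included."""
    ok = np.isfinite(values)
    flags = np.zeros(values.shape, dtype=bool)
    n = int(ok.sum())
    if n == 0:
        return flags
    k = int(np.ceil(top_frac * n))
    threshold = np.sort(values[ok])[::-1][k - 1]
    flags[ok] = values[ok] >= threshold
    return flags


def snp_selection_stats(
    site_ids: Sequence[str],
    chrom: np.ndarray,
    pos: np.ndarray,
    ihs_values: np.ndarray,
    lsbl_values: np.ndarray,
    top_frac: float = 0.05,
) -> pd.DataFrame:
    """Assemble per-SNP stats: empirical p's, F_CS and top-5% outlier flags."""
    p_ihs = empirical_p(ihs_values, side="two")
    p_lsbl = empirical_p(lsbl_values, side="upper")
    f = fcs(p_ihs, p_lsbl)
    table = pd.DataFrame(
        {
            "site_id": list(site_ids),
            "chrom": chrom,
            "pos": pos,
            "ihs": ihs_values,
            "lsbl": lsbl_values,
            "p_ihs": p_ihs,
            "p_lsbl": p_lsbl,
            "fcs": f,
        }
    )
    table["outlier"] = _top_frac_flags(f, top_frac)
    table.loc[~np.isfinite(f), "outlier"] = False
    return table


def window_outliers(
    stats: pd.DataFrame,
    window_bp: int = 100_000,
    min_snps: int = 10,
    n_bins: int = 4,
    top_frac: float = 0.05,
) -> pd.DataFrame:
    """Call selected 100-kb windows from per-SNP outlier flags.

    Non-overlapping windows anchored at multiples of ``window_bp``; windows
    with fewer than ``min_snps`` SNPs (with defined F_CS) are discarded; the
    rest are split into ``n_bins`` SNP-count quantile bins and, within each
    bin, windows whose outlier-SNP proportion is in the top ``top_frac``
    (ties included) are flagged selected.
    """
    s = stats[np.isfinite(stats["fcs"])].copy()
    s["win"] = (s["pos"] - 1) // window_bp
    grouped = s.groupby(["chrom", "win"], sort=True)
    table = grouped.agg(
        n_snps=("site_id", "size"), n_outlier=("outlier", "sum")
    ).reset_index()
    table = table[table["n_snps"] >= min_snps].reset_index(drop=True)
    table["start"] = table["win"] * window_bp
    table["end"] = table["start"] + window_bp
    table["prop_outlier"] = table["n_outlier"] / table["n_snps"]
    if len(table) == 0:
        table["bin"] = pd.Series([], dtype=int)
        table["selected"] = pd.Series([], dtype=bool)
        return table[
            ["chrom", "start", "end", "n_snps", "n_outlier", "prop_outlier", "bin", "selected"]
        ]
    # SNP-count quartile bins (duplicate edges merged for skewed counts)
    try:
        table["bin"] = pd.qcut(table["n_snps"], q=n_bins, labels=False, duplicates="drop")
    except ValueError:
        table["bin"] = 0
    table["bin"] = table["bin"].fillna(0).astype(int)
    table["selected"] = False
    for b in table["bin"].unique():
        mask = table["bin"] == b
        flags = _top_frac_flags(table.loc[mask, "prop_outlier"].to_numpy(), top_frac)
        table.loc[mask, "selected"] = flags
    return table[
        ["chrom", "start", "end", "n_snps", "n_outlier", "prop_outlier", "bin", "selected"]
    ]
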