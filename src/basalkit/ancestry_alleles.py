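"""Detection of basal-Asian (bASN) derived alleles and ancient genetic scores.

The detection is a two-stage frequency/LD screen: seed alleles are derived
alleles common (> 0.2) in at least one representative tropical indigenous
Asian (TIA) population yet rare (< 0.1) in every nonindigenous European and
East Asian population; the set is then expanded by linkage, adding derived
alleles within 500 kb of a seed with r^2 > 0.5 to it over the pooled TIA
haplotypes.  Detected alleles are chained into blocks wherever consecutive
alleles lie within 500 kb, and ancient samples receive a genetic score (GS):
the fraction of genotyped bASN sites at which the sample carries the derived
allele, either unweighted over sites or averaged within blocks first.  The
GS-vs-age trend is an OLS regression with latitude, longitude and ten PC
covariates, after dropping samples whose genotyped-SNP count falls below the
first quartile of the cohort.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import HaplotypeMatrix, PopulationPanel

logger = logging.getLogger("basalkit")

MISSING = -1  # pseudo-haploid missing code


@dataclasses.dataclass
class BasnAlleleSet:
    """Detected bASN-derived alleles, sorted by (chrom, pos), with blocks."""

    table: pd.DataFrame  # columns: site_id, chrom, pos, allele, stage, block_id

    def __post_init__(self) -> None:
        required = {"site_id", "chrom", "pos", "allele", "stage"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"allele table needs columns {sorted(required)}")

    @property
    def site_ids(self) -> list[str]:
        return self.table["site_id"].tolist()

    @property
    def n_blocks(self) -> int:
        return int(self.table["block_id"].nunique())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BasnAlleleSet":
        return cls(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def ld_r2(
    geno: HaplotypeMatrix,
    site_a: str | int,
    site_b: str | int,
    rows: np.ndarray | None = None,
) -> float:
    """Squared correlation of derived-allele indicators over haplotypes.

    Monomorphic sites (within the scope) give 0.
    """
    ia = geno.site_index(site_a) if isinstance(site_a, str) else site_a
    ib = geno.site_index(site_b) if isinstance(site_b, str) else site_b
    h = geno.haplotypes if rows is None else geno.haplotypes[rows]
    x = h[:, ia].astype(float)
    y = h[:, ib].astype(float)
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return 0.0
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov**2 / (vx * vy))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def identify_basn_alleles(
    geno: HaplotypeMatrix,
    panel: PopulationPanel,
    tia_pops: Sequence[str],
    ref_pops: Sequence[str],
    f_hi: float = 0.2,
    f_lo: float = 0.1,
    ld_r2_min: float = 0.5,
    ld_window_bp: int = 500_000,
    block_gap_bp: int = 500_000,
) -> BasnAlleleSet:
    """Two-stage bASN-derived allele screen (frequency contrast + LD expansion).

    Thresholds are strict inequalities: seed alleles have derived AF > ``f_hi``
    in at least one TIA population and < ``f_lo`` in every reference
    population; stage 2 adds alleles with r^2 > ``ld_r2_min`` to a seed within
    ``ld_window_bp``, computed over the pooled TIA haplotypes, without
    transitive chaining.  Unpolarized sites are skipped with a logged count.
    """
    polar = geno.polarized_mask
    n_skipped = int((~polar).sum())
    if n_skipped:
        logger.info("identify_basn_alleles: skipped %d unpolarized site(s)", n_skipped)

    tia_rows = {p: geno.sample_haplotype_rows(panel.samples_of(p)) for p in tia_pops}
    ref_rows = {p: geno.sample_haplotype_rows(panel.samples_of(p)) for p in ref_pops}
    tia_af = np.column_stack([geno.derived_freq(r) for r in tia_rows.values()])
    ref_af = np.column_stack([geno.derived_freq(r) for r in ref_rows.values()])

    seed_mask = polar & (tia_af > f_hi).any(axis=1) & (ref_af < f_lo).all(axis=1)

    pooled = np.concatenate(list(tia_rows.values()))
    haps = geno.haplotypes[pooled].astype(np.float64)
    pos = geno.positions
    chroms = np.array([s.chrom for s in geno.sites])

    linked_mask = np.zeros(geno.n_sites, dtype=bool)
    seed_idx = np.flatnonzero(seed_mask)
    # standardized haplotype columns for fast r^2 against seed columns
    mean = haps.mean(axis=0)
    sd = haps.std(axis=0)
    ok = sd > 0
    z = np.zeros_like(haps)
    z[:, ok] = (haps[:, ok] - mean[ok]) / sd[ok]
    nh = haps.shape[0]
    for si in seed_idx:
        near = (
            (chroms == chroms[si])
            & (np.abs(pos - pos[si]) <= ld_window_bp)
            & polar
            & ~seed_mask
            & ~linked_mask
        )
        cand = np.flatnonzero(near)
        if cand.size == 0:
            continue
        r = z[:, cand].T @ z[:, si] / nh
        linked_mask[cand[r**2 > ld_r2_min]] = True

    detected = np.flatnonzero(seed_mask | linked_mask)
    table = pd.DataFrame(
        {
            "site_id": [geno.sites[i].site_id for i in detected],
            "chrom": chroms[detected],
            "pos": pos[detected],
            "allele": [geno.sites[i].derived_allele for i in detected],
            "stage": np.where(seed_mask[detected], "seed", "linked"),
        }
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    alleles = BasnAlleleSet(table)
    return assign_blocks(alleles, gap_bp=block_gap_bp)


def assign_blocks(alleles: BasnAlleleSet, gap_bp: int = 500_000) -> BasnAlleleSet:
    """Single-linkage chaining: consecutive alleles <= gap_bp apart share a block."""
    t = alleles.table.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if len(t) == 0:
        t["block_id"] = pd.Series([], dtype=int)
        return BasnAlleleSet(t)
    new_block = (t["chrom"] != t["chrom"].shift()) | (
        t["pos"] - t["pos"].shift() > gap_bp
    )
    t["block_id"] = new_block.cumsum().astype(int)
    return BasnAlleleSet(t)


# ---------------------------------------------------------------------------
# genetic scores
# ---------------------------------------------------------------------------

def _calls_for(sample_row: pd.Series, site_ids: Sequence[str]) -> np.ndarray:
    return sample_row[list(site_ids)].to_numpy(dtype=float)


def gs_unweighted(sample_row: pd.Series, alleles: BasnAlleleSet) -> float:
    """Mean derived-allele presence over the sample's genotyped bASN sites."""
    d = _calls_for(sample_row, alleles.site_ids)
    genotyped = d != MISSING
    m = int(genotyped.sum())
    if m == 0:
        raise ValueError("sample has no genotyped bASN sites; GS undefined")
    return float(d[genotyped].mean())


def gs_weighted(sample_row: pd.Series, alleles: BasnAlleleSet) -> float:
    """Block-averaged GS: mean over blocks of the within-block presence mean.

    Blocks with no genotyped site are excluded from the block count N.
    """
    d = _calls_for(sample_row, alleles.site_ids)
    blocks = alleles.table["block_id"].to_numpy()
    genotyped = d != MISSING
    if not genotyped.any():
        raise ValueError("sample has no genotyped bASN sites; GS undefined")
    means = []
    for b in np.unique(blocks):
        mask = (blocks == b) & genotyped
        if mask.any():
            means.append(d[mask].mean())
    return float(np.mean(means))


def gs_table(cohort: pd.DataFrame, alleles: BasnAlleleSet, weighted: bool = False) -> pd.DataFrame:
    """Per-sample GS and genotyped-SNP count for a pseudo-haploid cohort table."""
    scorer = gs_weighted if weighted else gs_unweighted
    calls = cohort[alleles.site_ids].to_numpy()
    m = (calls != MISSING).sum(axis=1)
    out = cohort.drop(columns=alleles.site_ids).copy()
    out["n_genotyped"] = m
    gs = np.full(len(cohort), np.nan)
    for i in range(len(cohort)):
        if m[i] > 0:
            gs[i] = scorer(cohort.iloc[i], alleles)
    out["gs"] = gs
    return out


@dataclasses.dataclass
class GsRegressionFit:
    """OLS fit of GS on age with geographic and PC covariates."""

    params: pd.Series
    bse: pd.Series  # classical standard errors
    bse_robust: pd.Series  # HC1
    pvalues: pd.Series
    conf_int: pd.DataFrame
    n_used: int
    excluded: list[str]

    @property
    def beta_time(self) -> float:
        return float(self.params["date"])


def gs_time_regression(
    cohort: pd.DataFrame,
    alleles: BasnAlleleSet,
    weighted: bool = False,
    min_samples: int = 14,
) -> GsRegressionFit:
    """Regress GS on sample age with lat/lon/PC covariates.

    Samples whose genotyped-SNP count is strictly below the first quartile
    (25th percentile, linear interpolation) of the cohort are excluded before
    fitting; samples with zero genotyped sites are likewise excluded.
    """
    import statsmodels.api as sm

    scored = gs_table(cohort, alleles, weighted=weighted)
    q1 = np.quantile(scored["n_genotyped"], 0.25)
    keep = (scored["n_genotyped"] >= q1) & scored["gs"].notna()
    excluded = scored.loc[~keep, "sample_id"].tolist()
    sub = scored[keep]
    pc_cols = [c for c in cohort.columns if c.startswith("PC")]
    x_cols = ["date", "lat", "lon"] + pc_cols
    if len(sub) < min_samples:
        raise ValueError(
            f"only {len(sub)} samples after first-quartile exclusion; need >= {min_samples}"
        )
    X = sm.add_constant(sub[x_cols].to_numpy(dtype=float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name columns that add no rank
        names = ["const"] + x_cols
        bad = []
        rank = 0
        for j in range(X.shape[1]):
            r = np.linalg.matrix_rank(X[:, : j + 1])
            if r == rank:
                bad.append(names[j])
            rank = r
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(sub["gs"].to_numpy(dtype=float), X).fit()
    robust = fit.get_robustcov_results(cov_type="HC1")
    names = ["const"] + x_cols
    ci = pd.DataFrame(fit.conf_int(), index=names, columns=["lo", "hi"])
    return GsRegressionFit(
        params=pd.Series(fit.params, index=names),
        bse=pd.Series(fit.bse, index=names),
        bse_robust=pd.Series(robust.bse, index=names),
        pvalues=pd.Series(fit.pvalues, index=names),
        conf_int=ci,
        n_used=int(fit.nobs),
        excluded=excluded,
    )
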