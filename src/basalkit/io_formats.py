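"""Readers/writers for the formats the pipeline touches and the shared domain types.

Internal coordinates are 1-based (VCF convention); every interval file written
by the package is BED 0-based half-open. Phased modern genotypes may not
contain missing calls — ancient pseudo-haploid data carry their own explicit
missing code and live in :mod:`basalkit.ancestry_alleles`.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("basalkit")

#: closed vocabulary for population categories in a sample panel
PANEL_CATEGORIES = frozenset(
    {
        "representative_TIA",
        "other_TIA",
        "nonindigenous_EUR",
        "nonindigenous_EAS",
        "nonindigenous_other",
        "AFR",
        "outgroup",
    }
)

UNKNOWN_ANCESTRAL = "."


@dataclasses.dataclass(frozen=True)
class SiteInfo:
    """A biallelic SNP with optional ancestral-allele and annotation fields."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    ancestral_allele: str = UNKNOWN_ANCESTRAL
    site_id: str = ""
    gerp: float | None = None
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos} at {self.site_id!r}")
        aa = self.ancestral_allele
        if aa != UNKNOWN_ANCESTRAL and aa not in (self.ref_allele, self.alt_allele):
            raise ValueError(
                f"ancestral allele {aa!r} at {self.chrom}:{self.pos} matches neither "
                f"REF {self.ref_allele!r} nor ALT {self.alt_allele!r}"
            )

    @property
    def polarized(self) -> bool:
        return self.ancestral_allele != UNKNOWN_ANCESTRAL

    @property
    def derived_allele(self) -> str:
        """Allele coded 1 in a HaplotypeMatrix (ALT when ancestral unknown)."""
        if self.ancestral_allele == self.ref_allele:
            return self.alt_allele
        if self.ancestral_allele == self.alt_allele:
            return self.ref_allele
        return self.alt_allele


class HaplotypeMatrix:
    """Phased haplotypes coded 0 = ancestral, 1 = derived.

    Rows are haplotypes (two consecutive rows per sample, in ``sample_ids``
    order); columns are sites sorted by (chrom, pos). At sites whose
    ancestral allele is unknown the coding falls back to ALT dosage and the
    site is excluded from any polarized statistic by the callers.
    """

    def __init__(
        self,
        sites: Sequence[SiteInfo],
        haplotypes: np.ndarray,
        sample_ids: Sequence[str],
    ) -> None:
        haplotypes = np.asarray(haplotypes, dtype=np.int8)
        if haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D (haplotypes x sites)")
        if haplotypes.shape[0] % 2 != 0:
            raise ValueError("haplotype count must be even (two per sample)")
        if haplotypes.shape[0] != 2 * len(sample_ids):
            raise ValueError(
                f"{haplotypes.shape[0]} haplotypes for {len(sample_ids)} samples"
            )
        if haplotypes.shape[1] != len(sites):
            raise ValueError("site count mismatch with haplotype columns")
        if not np.isin(haplotypes, (0, 1)).all():
            raise ValueError("haplotype codes must be 0 or 1")
        ids = [s.site_id for s in sites]
        if len(set(ids)) != len(ids):
            raise ValueError("site_id values must be unique")
        last: tuple[str, int] | None = None
        for s in sites:
            key = (s.chrom, s.pos)
            if last is not None and last[0] == s.chrom and key[1] <= last[1]:
                raise ValueError(
                    f"sites not strictly increasing within chromosome at {s.chrom}:{s.pos}"
                )
            last = key
        self.sites = list(sites)
        self.haplotypes = haplotypes
        self.sample_ids = list(sample_ids)

    # -- basic accessors -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def polarized_mask(self) -> np.ndarray:
        return np.array([s.polarized for s in self.sites], dtype=bool)

    def site_index(self, site_id: str) -> int:
        try:
            return self._site_lookup[site_id]
        except AttributeError:
            self._site_lookup = {s.site_id: i for i, s in enumerate(self.sites)}
            return self._site_lookup[site_id]

    def sample_haplotype_rows(self, samples: Iterable[str]) -> np.ndarray:
        """Row indices of the haplotypes belonging to the given samples."""
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows: list[int] = []
        for s in samples:
            if s not in idx:
                raise KeyError(f"sample {s!r} not in matrix")
            rows.extend((2 * idx[s], 2 * idx[s] + 1))
        return np.array(rows, dtype=np.intp)

    def derived_freq(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Derived-allele frequency per site over the given haplotype rows."""
        h = self.haplotypes if rows is None else self.haplotypes[rows]
        return h.mean(axis=0)

    def diploid_counts(self) -> np.ndarray:
        """n_samples x n_sites matrix of per-sample derived-allele counts (0/1/2)."""
        return (
            self.haplotypes[0::2].astype(np.int16) + self.haplotypes[1::2]
        )


@dataclasses.dataclass
class PopulationPanel:
    """sample -> population and population -> category maps."""

    sample_to_pop: dict[str, str]
    pop_to_category: dict[str, str]

    def __post_init__(self) -> None:
        bad = set(self.pop_to_category.values()) - PANEL_CATEGORIES
        if bad:
            raise ValueError(
                f"unknown categories {sorted(bad)}; allowed: {sorted(PANEL_CATEGORIES)}"
            )
        missing = {p for p in self.sample_to_pop.values() if p not in self.pop_to_category}
        if missing:
            raise ValueError(f"populations without a category: {sorted(missing)}")

    def samples_of(self, population: str) -> list[str]:
        if population not in self.pop_to_category:
            raise KeyError(f"population {population!r} not in panel")
        return [s for s, p in self.sample_to_pop.items() if p == population]

    def populations(self, category: str | None = None) -> list[str]:
        if category is None:
            return sorted(self.pop_to_category)
        return sorted(p for p, c in self.pop_to_category.items() if c == category)

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        missing = [s for s in sample_ids if s not in self.sample_to_pop]
        if missing:
            raise ValueError(f"samples absent from panel: {missing[:5]}...")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, ancestral_tag: str = "AA") -> HaplotypeMatrix:
    """Read a phased biallelic-SNP VCF into derived-allele coding.

    The ancestral allele is taken from INFO/<ancestral_tag>; records without
    it (or with an allele matching neither REF nor ALT) are retained with the
    unknown flag and coded by ALT dosage. Multiallelic or unphased records
    raise.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    sites: list[SiteInfo] = []
    columns: list[np.ndarray] = []
    n_unknown = 0
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {var.CHROM}:{var.POS} ({var.REF}->{var.ALT})"
            )
        gts = np.array(var.genotypes)  # (n_samples, 3): a0, a1, phased
        if not gts[:, 2].all():
            raise ValueError(f"unphased genotype at {var.CHROM}:{var.POS}")
        if (gts[:, :2] < 0).any():
            raise ValueError(f"missing genotype at {var.CHROM}:{var.POS}")
        alt_dosage = gts[:, :2].reshape(-1)  # haplotype-major: s0h0, s0h1, ...
        aa = var.INFO.get(ancestral_tag)
        if aa is not None:
            aa = str(aa).upper().rstrip("|").split("|")[0]
        if aa not in (var.REF, var.ALT[0]):
            aa = UNKNOWN_ANCESTRAL
            n_unknown += 1
        codes = alt_dosage if aa in (var.REF, UNKNOWN_ANCESTRAL) else 1 - alt_dosage
        sites.append(
            SiteInfo(
                chrom=var.CHROM,
                pos=var.POS,
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
                ancestral_allele=aa,
                site_id=var.ID or f"{var.CHROM}_{var.POS}",
            )
        )
        columns.append(codes.astype(np.int8))
    if n_unknown:
        logger.info("read_vcf: %d site(s) with unknown ancestral allele", n_unknown)
    haps = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((2 * len(sample_ids), 0), dtype=np.int8)
    )
    return HaplotypeMatrix(sites, haps, sample_ids)


def write_vcf(matrix: HaplotypeMatrix, path: str | Path, ancestral_tag: str = "AA") -> None:
    """Write the matrix back to an uncompressed phased VCF (derived coding inverted)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            f'##INFO=<ID={ancestral_tag},Number=1,Type=String,Description="Ancestral allele">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in matrix.sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j, site in enumerate(matrix.sites):
            codes = matrix.haplotypes[:, j]
            if site.ancestral_allele == site.alt_allele:
                alt_dosage = 1 - codes
            else:
                alt_dosage = codes
            info = (
                f"{ancestral_tag}={site.ancestral_allele}" if site.polarized else "."
            )
            gts = "\t".join(
                f"{alt_dosage[2 * i]}|{alt_dosage[2 * i + 1]}"
                for i in range(matrix.n_samples)
            )
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.site_id}\t{site.ref_allele}\t"
                f"{site.alt_allele}\t.\t.\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# TSV / BED
# ---------------------------------------------------------------------------

def read_panel(path: str | Path) -> PopulationPanel:
    """Read a sample panel TSV with columns sample, population, category."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "population", "category"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel must have columns {sorted(required)}")
    pop_cat: dict[str, str] = {}
    for pop, cat in zip(df["population"], df["category"]):
        if pop in pop_cat and pop_cat[pop] != cat:
            raise ValueError(f"population {pop!r} mapped to two categories")
        pop_cat[pop] = cat
    return PopulationPanel(dict(zip(df["sample"], df["population"])), pop_cat)


def write_panel(panel: PopulationPanel, path: str | Path) -> None:
    rows = [
        {"sample": s, "population": p, "category": panel.pop_to_category[p]}
        for s, p in panel.sample_to_pop.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sites_table(path: str | Path) -> pd.DataFrame:
    """Per-site annotation TSV keyed by site_id (gerp and/or gene columns)."""
    df = pd.read_csv(path, sep="\t")
    if "site_id" not in df.columns:
        raise ValueError("sites table must have a site_id column")
    if df["site_id"].duplicated().any():
        raise ValueError("duplicate site_id in sites table")
    return df.set_index("site_id")


def write_bed(intervals: Iterable[tuple[str, int, int]] | pd.DataFrame, path: str | Path) -> None:
    """Write (chrom, start, end) intervals as BED (0-based half-open)."""
    if isinstance(intervals, pd.DataFrame):
        intervals = intervals[["chrom", "start", "end"]].itertuples(index=False)
    with Path(path).open("w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{int(start)}\t{int(end)}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={0: str},
    )
    return df.astype({"start": np.int64, "end": np.int64})


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gene_intervals(path: str | Path) -> pd.DataFrame:
    """BED with a 4th name column -> gene intervals (1-based inclusive internally)."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene"],
    )
    df["start"] = df["start"].astype(np.int64) + 1  # to 1-based inclusive
    df["end"] = df["end"].astype(np.int64)
    return df
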