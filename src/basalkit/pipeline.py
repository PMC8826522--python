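"""End-to-end orchestration: simulate -> detect -> score -> scan -> load -> report.

A run is driven by a :class:`RunConfig` (lossless JSON round trip, unknown
keys rejected).  Every stage writes its tables under the output directory
and records a manifest entry (records written, SHA-256 of the file); a rerun
with the same config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import ancestry_alleles, differentiation, load_model, selection_scan, synthetic_data
from .io_formats import write_bed, write_panel, write_tsv, write_vcf


@dataclasses.dataclass
class RunConfig:
    """All knobs of a demo pipeline run; defaults mirror the module defaults."""

    seed: int = 0
    out_dir: str = "basalkit_run"
    tia_pops: Sequence[str] = ("ADM", "MLS", "PHI", "PNG")
    ref_pops: Sequence[str] = ("EUR", "EAS")
    f_hi: float = 0.2
    f_lo: float = 0.1
    ld_r2_min: float = 0.5
    ld_window_bp: int = 500_000
    block_gap_bp: int = 500_000
    n_sites: int = 1000
    n_basn_private_sites: int = 200
    samples_per_pop: int = 30
    fst: float = 0.02
    basn_admixture: float = 0.3
    n_ancient: int = 150
    scan_n_haplotypes: int = 120
    scan_n_sites: int = 800
    scan_span_bp: int = 2_000_000
    region_bp: int = 50_000

    def __post_init__(self) -> None:
        # normalize sequence fields so a JSON round trip compares equal
        self.tia_pops = tuple(self.tia_pops)
        self.ref_pops = tuple(self.ref_pops)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def pct_basn(n_basn: int, n_total: int) -> float:
    """Percentage of bASN SNPs in a region, rounded half-up to one decimal."""
    if n_total <= 0:
        raise ValueError("region must contain at least one SNP")
    pct = Decimal(100 * n_basn) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def load_bundled_region_table() -> pd.DataFrame:
    """Curated 20-region summary (50-kb spans with total and bASN SNP counts).

    The % bASN column is recomputed from the counts at load time.
    """
    with resources.files("basalkit.data").joinpath("top_basn_regions.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    table["pct_basn"] = [
        pct_basn(b, t) for b, t in zip(table["n_basn_snps"], table["n_total_snps"])
    ]
    return table


def region_basn_density(
    af_table: pd.DataFrame,
    alleles: ancestry_alleles.BasnAlleleSet,
    tia_pops: Sequence[str],
    region_bp: int = 50_000,
    min_block_alleles: int = 5,
) -> pd.DataFrame:
    """Per-region bASN density report (50-kb non-overlapping regions).

    For each region: total SNPs, bASN SNPs, % bASN (one decimal, half-up),
    then per population the bASN SNP count, the mean over block-mean
    derived AFs (f_mean) and the maximum AF over blocks holding at least
    ``min_block_alleles`` bASN alleles (f_max).  ``af_table`` must carry
    site_id, pos and one AF column per population.
    """
    af = af_table.set_index("site_id")
    regions = (af["pos"].to_numpy() - 1) // region_bp
    af = af.assign(region=regions)
    basn = alleles.table.set_index("site_id")
    rows = []
    for region, sub in af.groupby("region"):
        in_basn = sub.index.intersection(basn.index)
        rec = {
            "start": int(region) * region_bp,
            "end": (int(region) + 1) * region_bp,
            "n_total_snps": len(sub),
            "n_basn_snps": len(in_basn),
            "pct_basn": pct_basn(len(in_basn), len(sub)),
        }
        for pop in tia_pops:
            if len(in_basn) == 0:
                rec[f"{pop}_n"] = 0
                rec[f"{pop}_f_mean"] = np.nan
                rec[f"{pop}_f_max"] = np.nan
                continue
            sub_basn = sub.loc[in_basn]
            blocks = basn.loc[in_basn, "block_id"]
            block_means = sub_basn.groupby(blocks)[pop].mean()
            block_sizes = basn.loc[in_basn].groupby("block_id").size()
            big = block_sizes[block_sizes >= min_block_alleles].index
            rec[f"{pop}_n"] = int((sub_basn[pop] > 0).sum())
            rec[f"{pop}_f_mean"] = float(block_means.mean())
            rec[f"{pop}_f_max"] = (
                float(sub_basn.loc[blocks.isin(big), pop].max()) if len(big) else np.nan
            )
        rows.append(rec)
    out = pd.DataFrame(rows).sort_values("start").reset_index(drop=True)
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full demo pipeline and return the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(cfg), "stages": []}

    def record(stage: str, path: Path, n_records: int) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "output": str(path),
                "n_records": int(n_records),
                "sha256": _sha256(path),
            }
        )

    # 1. simulate structured frequencies
    demo = synthetic_data.DemographyConfig(
        sample_sizes=(cfg.samples_per_pop,) * 6,
        n_sites=cfg.n_sites,
        fst=cfg.fst,
        basn_admixture=(cfg.basn_admixture,) * 4 + (0.0, 0.0),
        n_basn_private_sites=cfg.n_basn_private_sites,
        seed=cfg.seed,
    )
    af, matrix, panel, truth = synthetic_data.simulate_structured_frequencies(demo)
    vcf_path = out / "simulated.vcf"
    write_vcf(matrix, vcf_path)
    record("simulate:vcf", vcf_path, matrix.n_sites)
    panel_path = out / "panel.tsv"
    write_panel(panel, panel_path)
    record("simulate:panel", panel_path, len(panel.sample_to_pop))
    truth_path = out / "basn_truth.tsv"
    write_tsv(truth, truth_path)
    record("simulate:truth", truth_path, len(truth))

    # 2. differentiation
    pops = list(cfg.tia_pops) + list(cfg.ref_pops)
    dist = differentiation.pairwise_fst_matrix(matrix, panel, pops)
    dist_path = out / "fst_matrix.tsv"
    dist.to_csv(dist_path, sep="\t")
    record("fst:matrix", dist_path, len(dist))
    newick = differentiation.nj_tree(dist, outgroup=None)
    tree_path = out / "fst_nj.nwk"
    tree_path.write_text(newick + "\n")
    record("fst:tree", tree_path, 1)

    # 3. bASN detection + blocks
    alleles = ancestry_alleles.identify_basn_alleles(
        matrix,
        panel,
        cfg.tia_pops,
        cfg.ref_pops,
        f_hi=cfg.f_hi,
        f_lo=cfg.f_lo,
        ld_r2_min=cfg.ld_r2_min,
        ld_window_bp=cfg.ld_window_bp,
        block_gap_bp=cfg.block_gap_bp,
    )
    alleles_path = out / "basn_alleles.tsv"
    alleles.to_tsv(alleles_path)
    record("basn:alleles", alleles_path, len(alleles.table))

    # 4. ancient cohort + GS regression
    cohort = synthetic_data.simulate_ancient_cohort(
        synthetic_data.AncientCohortConfig(n_samples=cfg.n_ancient, seed=cfg.seed + 1),
        alleles.site_ids,
    )
    cohort_path = out / "ancient_cohort.tsv"
    write_tsv(cohort, cohort_path)
    record("ancient:cohort", cohort_path, len(cohort))
    east = cohort[cohort["region"] == "East"].reset_index(drop=True)
    fit = ancestry_alleles.gs_time_regression(east, alleles, weighted=True)
    fit_path = out / "gs_fit.json"
    fit_path.write_text(
        json.dumps(
            {
                "beta_time": fit.beta_time,
                "se_time": float(fit.bse["date"]),
                "se_time_robust": float(fit.bse_robust["date"]),
                "p_time": float(fit.pvalues["date"]),
                "n_used": fit.n_used,
                "n_excluded": len(fit.excluded),
            },
            indent=2,
        )
        + "\n"
    )
    record("ancient:gs_fit", fit_path, 1)

    # 5. selection scan on a sweep dataset
    sweep_cfg = synthetic_data.SweepConfig(
        n_haplotypes=cfg.scan_n_haplotypes,
        n_sites=cfg.scan_n_sites,
        span_bp=cfg.scan_span_bp,
        seed=cfg.seed + 2,
    )
    focal, truth_sweep, ref_counts, out_counts = synthetic_data.simulate_scan_dataset(
        sweep_cfg
    )
    ihs_table = selection_scan.ihs(focal)
    n_focal = focal.n_haplotypes
    focal_counts = focal.haplotypes.sum(axis=0)
    lsbl_values = selection_scan.lsbl(
        differentiation.pairwise_per_site_fst(
            focal_counts, n_focal, ref_counts[:, 0], ref_counts[0, 1]
        ),
        differentiation.pairwise_per_site_fst(
            focal_counts, n_focal, out_counts[:, 0], out_counts[0, 1]
        ),
        differentiation.pairwise_per_site_fst(
            ref_counts[:, 0], ref_counts[0, 1], out_counts[:, 0], out_counts[0, 1]
        ),
    )
    stats = selection_scan.snp_selection_stats(
        [s.site_id for s in focal.sites],
        np.array([s.chrom for s in focal.sites]),
        focal.positions,
        ihs_table["ihs"].to_numpy(),
        np.asarray(lsbl_values),
    )
    stats_path = out / "scan_snps.tsv"
    write_tsv(stats, stats_path)
    record("scan:snps", stats_path, len(stats))
    windows = selection_scan.window_outliers(stats)
    win_path = out / "scan_windows.tsv"
    write_tsv(windows, win_path)
    record("scan:windows", win_path, len(windows))
    sel = windows[windows["selected"]]
    bed_path = out / "scan_selected.bed"
    write_bed(sel[["chrom", "start", "end"]], bed_path)
    record("scan:selected_bed", bed_path, len(sel))

    # 6. mutation load (synthetic GERP scores keyed to the frequency table)
    rng = np.random.default_rng(cfg.seed + 3)
    gerp = pd.Series(
        rng.uniform(0.0, 8.0, size=len(af)), index=af["site_id"], name="gerp"
    )
    load_table = load_model.site_load_table(
        af.set_index("site_id"), gerp, list(cfg.tia_pops) + list(cfg.ref_pops)
    )
    load_path = out / "load_sites.tsv"
    load_table.to_csv(load_path, sep="\t")
    record("load:sites", load_path, len(load_table))
    load_summary = pd.DataFrame(
        [load_model.aggregate_load(load_table, p) for p in pops]
    )
    load_sum_path = out / "load_summary.tsv"
    write_tsv(load_summary, load_sum_path)
    record("load:summary", load_sum_path, len(load_summary))

    # 7. report
    density = region_basn_density(af, alleles, cfg.tia_pops, region_bp=cfg.region_bp)
    density_path = out / "region_density.tsv"
    write_tsv(density, density_path)
    record("report:region_density", density_path, len(density))

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def report(run_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Summary tables of a completed run: region density, GS fit, top windows, load."""
    run_dir = Path(run_dir)
    out: dict[str, pd.DataFrame] = {}
    out["region_density"] = pd.read_csv(run_dir / "region_density.tsv", sep="\t")
    out["gs_fit"] = pd.DataFrame([json.loads((run_dir / "gs_fit.json").read_text())])
    windows = pd.read_csv(run_dir / "scan_windows.tsv", sep="\t")
    out["top_windows"] = (
        windows.sort_values("prop_outlier", ascending=False).head(20).reset_index(drop=True)
    )
    out["load_summary"] = pd.read_csv(run_dir / "load_summary.tsv", sep="\t")
    return out
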