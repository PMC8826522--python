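"""Synthetic genotype generators with known ground truth.

Three generators cover the three test surfaces of the pipeline:

* :func:`simulate_structured_frequencies` — unlinked sites under the
  Balding–Nichols model, optionally with an admixed basal-Asian (bASN)
  lineage carrying private derived alleles.  Used for frequency statistics
  (F_ST, LSBL, ancestry-allele detection, load).
* :func:`simulate_sweep_haplotypes` — linked haplotypes built as founder
  mosaics with recombination, optionally with an injected sweep whose
  carriers share an identical core haplotype.  Used for EHH/iHS.
* :func:`simulate_ancient_cohort` — dated pseudo-haploid ancient samples
  whose bASN-allele carriage trends with age in one region.  Used for the
  genetic-score regression.

Every generator is a pure function of (config, seed): a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import HaplotypeMatrix, PopulationPanel, SiteInfo


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DemographyConfig:
    """Balding–Nichols structured populations with an optional bASN lineage.

    ``fst`` is the per-population drift parameter F_k of the Balding–Nichols
    beta; ``basn_admixture`` is the admixture proportion alpha_k of the basal
    lineage into each population (0 for non-admixed reference populations).
    bASN-private derived alleles are absent outside the basal lineage and
    reach frequency alpha_k * q in admixed populations, where q is the
    allele's frequency on the basal lineage itself, drawn from
    ``basn_private_freq_range``.  Private variants of a deeply diverged
    lineage are old and therefore common within it, hence the near-fixed
    default range.
    """

    populations: Sequence[str] = ("ADM", "MLS", "PHI", "PNG", "EUR", "EAS")
    categories: Sequence[str] = (
        "representative_TIA",
        "representative_TIA",
        "representative_TIA",
        "representative_TIA",
        "nonindigenous_EUR",
        "nonindigenous_EAS",
    )
    sample_sizes: Sequence[int] = (50, 50, 50, 50, 50, 50)
    n_sites: int = 2000
    fst: Sequence[float] | float = 0.02
    basn_admixture: Sequence[float] | float = (0.3, 0.3, 0.3, 0.3, 0.0, 0.0)
    n_basn_private_sites: int = 500
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    basn_private_freq_range: tuple[float, float] = (0.8, 1.0)
    chrom: str = "1"
    site_spacing_bp: int = 10_000
    seed: int = 0

    def _as_vec(self, value, name: str) -> np.ndarray:
        v = np.broadcast_to(np.asarray(value, dtype=float), (len(self.populations),))
        return np.array(v)

    def validate(self) -> None:
        k = len(self.populations)
        if len(self.categories) != k or len(self.sample_sizes) != k:
            raise ValueError("populations, categories, sample_sizes must align")
        if min(self.sample_sizes) < 2:
            raise ValueError("sample sizes must be >= 2")
        F = self._as_vec(self.fst, "fst")
        if (F < 0).any() or (F >= 1).any():
            raise ValueError("drift parameter F must be in [0, 1)")
        a = self._as_vec(self.basn_admixture, "basn_admixture")
        if (a < 0).any() or (a > 1).any():
            raise ValueError("admixture proportions must be in [0, 1]")


@dataclasses.dataclass
class SweepConfig:
    """Founder-mosaic haplotypes with recombination and an optional sweep.

    ``recomb_rate`` is the population-scale haplotype-shuffling rate per bp:
    the per-site probability that a haplotype switches founder template is
    ``recomb_rate * gap_bp``, so pairwise haplotype identity decays over
    roughly ``1 / (2 * recomb_rate)`` bp.  The default 1e-5 makes background
    identity decay over tens of kilobases, the scale seen in human data.
    """

    n_haplotypes: int = 200
    n_sites: int = 1500
    span_bp: int = 3_000_000
    recomb_rate: float = 1e-5
    n_founders: int = 30
    selected_index: int | None = None  # default: middle site
    selected_freq: float | None = 0.5  # None => neutral, no sweep
    core_length_bp: int = 200_000
    chrom: str = "1"
    seed: int = 0

    def validate(self) -> None:
        if self.selected_freq is not None and not (0 < self.selected_freq < 1):
            raise ValueError("selected allele frequency must be in (0, 1)")
        if self.core_length_bp > self.span_bp:
            raise ValueError("core haplotype longer than simulated span")
        idx = self.resolved_selected_index
        if not (0 <= idx < self.n_sites):
            raise ValueError("selected site index out of range")

    @property
    def resolved_selected_index(self) -> int:
        return self.n_sites // 2 if self.selected_index is None else self.selected_index


@dataclasses.dataclass
class AncientCohortConfig:
    """Dated pseudo-haploid samples for the GS-vs-time regression.

    ``slope_east`` is the increase in bASN-carrier probability per year BP
    for East Eurasian samples (West is flat at ``base_rate``).  Per-sample
    missingness varies over ``missing_range`` so genotyped-SNP counts differ
    and the first-quantile filter is exercised.
    """

    n_samples: int = 200
    date_range: tuple[float, float] = (0.0, 50_000.0)
    frac_east: float = 0.5
    base_rate: float = 0.2
    slope_east: float = 1e-5  # carrier probability per year BP
    slope_west: float = 0.0
    missing_range: tuple[float, float] = (0.0, 0.6)
    n_pcs: int = 10
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.date_range
        if not (0 <= lo <= hi <= 50_000):
            raise ValueError("dates must lie in 0..50,000 years BP")
        mlo, mhi = self.missing_range
        if not (0 <= mlo <= mhi < 1):
            raise ValueError("missingness must be in [0, 1)")


# ---------------------------------------------------------------------------
# structured frequencies (Balding–Nichols)
# ---------------------------------------------------------------------------

def _bn_draw(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Population allele frequency around ancestral p with drift F."""
    if F == 0:
        return p.copy()
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    return rng.beta(a, b)


def simulate_structured_frequencies(
    cfg: DemographyConfig,
) -> tuple[pd.DataFrame, HaplotypeMatrix, PopulationPanel, pd.DataFrame]:
    """Simulate unlinked genotypes under population structure.

    Returns ``(af_table, matrix, panel, truth)`` where ``af_table`` holds the
    realized per-population derived-allele frequencies (one row per site) and
    ``truth`` lists the bASN-private sites with their basal-lineage frequency.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    pops = list(cfg.populations)
    F = cfg._as_vec(cfg.fst, "fst")
    alpha = cfg._as_vec(cfg.basn_admixture, "basn_admixture")
    n_bg = cfg.n_sites
    n_priv = cfg.n_basn_private_sites
    n_tot = n_bg + n_priv

    lo, hi = cfg.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=n_bg)
    qlo, qhi = cfg.basn_private_freq_range
    q_basn = rng.uniform(qlo, qhi, size=n_priv)

    # expected per-population frequency before drift
    # background sites: ancestral p everywhere; private: alpha_k * q
    freqs = np.empty((n_tot, len(pops)))
    for k in range(len(pops)):
        bg = _bn_draw(rng, p_anc, F[k])
        if alpha[k] > 0:
            priv_mean = np.clip(alpha[k] * q_basn, 1e-9, 1 - 1e-9)
            priv = _bn_draw(rng, priv_mean, F[k])
        else:
            priv = np.zeros(n_priv)
        freqs[:n_bg, k] = bg
        freqs[n_bg:, k] = priv

    # site metadata: background then private, interleaved along the chromosome
    order = rng.permutation(n_tot)
    inv = np.argsort(order)
    spacing = cfg.site_spacing_bp
    positions = spacing * (1 + np.arange(n_tot))
    is_private = np.zeros(n_tot, dtype=bool)
    is_private[n_bg:] = True
    # shuffled genomic order
    freqs = freqs[order]
    is_private = is_private[order]

    sites = [
        SiteInfo(
            chrom=cfg.chrom,
            pos=int(positions[j]),
            ref_allele="A",
            alt_allele="G",
            ancestral_allele="A",
            site_id=f"s{j}",
        )
        for j in range(n_tot)
    ]

    sample_ids: list[str] = []
    sample_to_pop: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    for k, pop in enumerate(pops):
        n = cfg.sample_sizes[k]
        ids = [f"{pop}_{i}" for i in range(n)]
        sample_ids.extend(ids)
        sample_to_pop.update({s: pop for s in ids})
        haps = rng.random((2 * n, n_tot)) < freqs[:, k]
        blocks.append(haps.astype(np.int8))
    matrix = HaplotypeMatrix(sites, np.vstack(blocks), sample_ids)
    panel = PopulationPanel(sample_to_pop, dict(zip(pops, cfg.categories)))

    af = pd.DataFrame(freqs, columns=pops)
    af.insert(0, "site_id", [s.site_id for s in sites])
    af.insert(1, "pos", positions)
    af["basn_private"] = is_private

    # q_basn follows original draw order; map to genomic slots of private sites
    priv_slots = np.flatnonzero(is_private)
    orig_idx = order[priv_slots] - n_bg
    truth = pd.DataFrame(
        {
            "site_id": [f"s{j}" for j in priv_slots],
            "pos": positions[priv_slots],
            "basn_freq": q_basn[orig_idx],
        }
    )
    return af, matrix, panel, truth


# ---------------------------------------------------------------------------
# sweep haplotypes
# ---------------------------------------------------------------------------

def simulate_sweep_haplotypes(
    cfg: SweepConfig,
) -> tuple[HaplotypeMatrix, dict]:
    """Simulate linked haplotypes, optionally with an injected sweep.

    Background haplotypes are mosaics of ``n_founders`` founder haplotypes
    with recombination-driven switching (probability ``recomb_rate * gap``
    between adjacent sites), giving genuine LD that decays with distance.
    If ``selected_freq`` is set, the closest-to-target number of carriers
    share one identical core haplotype over ``core_length_bp`` around the
    selected site and carry the derived allele there; outside the core they
    recombine back into the founder pool.

    Returns the matrix and a truth dict with the selected site and carrier rows.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_haplotypes, cfg.n_sites
    positions = np.sort(rng.choice(np.arange(1, cfg.span_bp + 1), size=m, replace=False))
    founder_freq = rng.uniform(0.05, 0.95, size=m)
    founders = (rng.random((cfg.n_founders, m)) < founder_freq).astype(np.int8)

    gaps = np.diff(positions, prepend=positions[0])
    switch_p = np.clip(cfg.recomb_rate * gaps, 0.0, 1.0)
    switch_p[0] = 1.0  # first site: fresh founder draw

    # mosaic founder index per haplotype per site
    switches = rng.random((n, m)) < switch_p
    founder_choice = rng.integers(0, cfg.n_founders, size=(n, m))
    fidx = np.empty((n, m), dtype=np.int64)
    cur = founder_choice[:, 0].copy()
    for j in range(m):
        cur = np.where(switches[:, j], founder_choice[:, j], cur)
        fidx[:, j] = cur
    haps = founders[fidx, np.arange(m)[None, :]]

    truth: dict = {"selected_index": None, "carriers": None, "positions": positions}
    if cfg.selected_freq is not None:
        sel = cfg.resolved_selected_index
        n_car = int(round(cfg.selected_freq * n))
        n_car = min(max(n_car, 1), n - 1)
        carriers = rng.choice(n, size=n_car, replace=False)
        core_lo = positions[sel] - cfg.core_length_bp // 2
        core_hi = positions[sel] + cfg.core_length_bp // 2
        # every carrier shares one haplotype over the core, then escapes it by
        # recombination at geometric (exponential) distances past the core
        # edges; recomb_rate = 0 keeps carriers identical over the whole span
        core_hap = haps[rng.integers(0, n)].copy()
        if cfg.recomb_rate > 0:
            ext_left = rng.exponential(1.0 / cfg.recomb_rate, size=n_car)
            ext_right = rng.exponential(1.0 / cfg.recomb_rate, size=n_car)
        else:
            ext_left = np.full(n_car, np.inf)
            ext_right = np.full(n_car, np.inf)
        for c, el, er in zip(carriers, ext_left, ext_right):
            shared = (positions >= core_lo - el) & (positions <= core_hi + er)
            haps[c, shared] = core_hap[shared]
        haps[:, sel] = 0
        haps[carriers, sel] = 1
        truth["selected_index"] = sel
        truth["carriers"] = np.sort(carriers)
        truth["core_interval"] = (int(max(core_lo, 1)), int(core_hi))

    if n % 2:
        raise ValueError("n_haplotypes must be even to form diploid samples")
    sites = [
        SiteInfo(
            chrom=cfg.chrom,
            pos=int(positions[j]),
            ref_allele="A",
            alt_allele="G",
            ancestral_allele="A",
            site_id=f"v{j}",
        )
        for j in range(m)
    ]
    sample_ids = [f"S{i}" for i in range(n // 2)]
    return HaplotypeMatrix(sites, haps, sample_ids), truth


def simulate_scan_dataset(
    cfg: SweepConfig,
    ref_fst: float = 0.02,
    out_fst: float = 0.1,
    n_ref_haps: int = 100,
    n_out_haps: int = 100,
    seed: int | None = None,
) -> tuple[HaplotypeMatrix, dict, np.ndarray, np.ndarray]:
    """Focal sweep haplotypes plus drifted reference/outgroup frequencies.

    The reference and outgroup populations drift (Balding–Nichols) from the
    focal background founder frequencies, so the sweep shifts the focal
    population's branch and elevates LSBL at the swept region.  Returns
    (focal matrix, truth, ref derived-allele counts, out derived-allele
    counts) with counts shaped (n_sites, 2) = (derived count, total).
    """
    matrix, truth = simulate_sweep_haplotypes(cfg)
    rng = np.random.default_rng(cfg.seed + 7_919 if seed is None else seed)
    base = matrix.derived_freq()  # post-sweep focal freq; use pre-sweep proxy
    anc = np.clip(base, 0.02, 0.98)
    ref_f = _bn_draw(rng, anc, ref_fst)
    out_f = _bn_draw(rng, anc, out_fst)
    ref = np.column_stack(
        [rng.binomial(n_ref_haps, ref_f), np.full(matrix.n_sites, n_ref_haps)]
    )
    out = np.column_stack(
        [rng.binomial(n_out_haps, out_f), np.full(matrix.n_sites, n_out_haps)]
    )
    return matrix, truth, ref, out


# ---------------------------------------------------------------------------
# ancient cohort
# ---------------------------------------------------------------------------

def simulate_ancient_cohort(
    cfg: AncientCohortConfig, basn_sites: Sequence[str]
) -> pd.DataFrame:
    """Simulate a dated pseudo-haploid ancient cohort over the given bASN sites.

    Returns a table with one row per sample: sample_id, date (years BP),
    region, lat, lon, PC1..PCn, then one column per bASN site holding the
    pseudo-haploid call (1 derived, 0 ancestral, -1 missing).  The
    bASN-carrier probability is ``base_rate + slope * date`` (clipped to
    [0, 1]) with the region-specific slope; covariates have zero true effect.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    dates = rng.uniform(*cfg.date_range, size=n)
    east = rng.random(n) < cfg.frac_east
    slope = np.where(east, cfg.slope_east, cfg.slope_west)
    prob = np.clip(cfg.base_rate + slope * dates, 0.0, 1.0)
    miss = rng.uniform(*cfg.missing_range, size=n)

    m = len(basn_sites)
    calls = (rng.random((n, m)) < prob[:, None]).astype(np.int8)
    missing_mask = rng.random((n, m)) < miss[:, None]
    calls[missing_mask] = -1

    df = pd.DataFrame(
        {
            "sample_id": [f"anc{i}" for i in range(n)],
            "date": dates,
            "region": np.where(east, "East", "West"),
            "lat": rng.uniform(-40, 70, size=n),
            "lon": rng.uniform(-10, 150, size=n),
        }
    )
    for j in range(cfg.n_pcs):
        df[f"PC{j + 1}"] = rng.normal(0.0, 1.0, size=n)
    calls_df = pd.DataFrame(calls, columns=list(basn_sites))
    return pd.concat([df, calls_df], axis=1)
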