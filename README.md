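# basalkit

Population-genomic statistics for studying **basal Asian (bASN) ancestry** —
a deeply diverged modern-human lineage enriched in tropical indigenous Asian
(TIA) populations such as the Andamanese, Malaysian and Philippine Negritos
and Papuans — and its functional footprint in selection, mutation load and
skin-pigmentation genetics. The package is aimed at population geneticists
who want the bespoke statistics of this analysis style as tested, reusable
code, exercisable end-to-end on bundled synthetic-data generators with known
ground truth.

## What it computes

**bASN-derived allele detection.** A two-stage screen over phased, polarized
genotypes: *seed* alleles are derived alleles with frequency > 0.2 in at
least one representative TIA population and < 0.1 in every nonindigenous
European/East Asian population; the set is expanded by linkage
disequilibrium, adding derived alleles within 500 kb of a seed with
r² > 0.5 over the pooled TIA haplotypes. Detected alleles are chained into
blocks wherever consecutive alleles are ≤ 500 kb apart.

**Genetic scores of ancient samples.** For a pseudo-haploid ancient sample
with presence indicator dᵢ at its m genotyped bASN sites,

    GS_unweighted = (1/m) Σᵢ dᵢ
    GS_weighted   = (1/N) Σⱼ (1/nⱼ) Σᵢ d_ij      (N blocks, nⱼ sites in block j)

and the age trend is an OLS fit GS = α + β_time·X_time + β_lat·X_lat +
β_lon·X_lon + β_PC1..PC10·X_PC, after excluding samples whose genotyped-SNP
count falls below the cohort's first quartile.

**Differentiation.** Weir–Cockerham (1984) variance components per SNP (any
number of populations, haplotype-level counts), genome-wide ratio-of-sums
weighting, 10-kb/1-kb sliding windows, per-gene top-window values with
sqrt-transform z-scores (outlier at z > 1.96), and a neighbor-joining
population tree from the pairwise weighted-F_ST matrix.

**Composite selection scan.** iHS = ln(iHH_A/iHH_D) from trapezoid-integrated
EHH curves (truncated at EHH < 0.05, standardized within derived-frequency
bins), LSBL = (d_FR + d_FO − d_RO)/2 from per-SNP pairwise F_ST, genome-wide
empirical p-values (|iHS| two-sided, LSBL upper tail), and

    F_CS = −log10 p_iHS − log10 p_LSBL.

Outlier SNPs are the top 5% of F_CS; selected regions are 100-kb windows
(≥ 10 SNPs) whose outlier-SNP proportion ranks in the top 5% of their
SNP-count quartile bin.

**Mutation load.** GERP-binned selection coefficients — (2,4] → −4.5×10⁻⁴,
(4,6] → −4.5×10⁻³, (>6) → −1×10⁻², h = 0.5 — and the additive per-site load
L = 2shf(1−f) + sf², SNP-averaged over gene sets per population. With
h = 0.5 the load is exactly s·f.

**Pigmentation.** Dark/light pigmentation allele (DPA/LPA) effect tables,
the unweighted DPA-count polygenic score, putative-DPA classification by
TIA-vs-Eurasian frequency contrast, a Fisher's-exact African-sharing
contingency test (conditional-MLE odds ratio, as in R's `fisher.test`), the
50-kb allele-frequency block screen around target variants, and the
carrier-preserving subsampler for haplotype-network construction.

**Synthetic data.** Balding–Nichols structured frequencies with an admixed
bASN lineage carrying private derived alleles; founder-mosaic haplotypes
with recombination and an injectable sweep (shared core haplotype); dated
pseudo-haploid ancient cohorts whose bASN carriage trends with age in East
Eurasia. All generators are pure functions of (config, seed).

## Worked example

```sh
python analysis/01_simulate.py
python analysis/03_detect_basn.py
python analysis/04_ancient_gs.py
```

prints, for the default simulated cohort (six populations of 50 samples,
2,500 sites of which 500 are bASN-private, admixture α = 0.3):

```
detected 505 bASN-derived alleles in 1 blocks
recall of truth-private sites: 0.998
false seed fraction: 0.012
...
region         gs  beta_time        se  se_robust         p  n_used
  East unweighted  9.907e-06 1.563e-07  1.605e-07 2.423e-81     112
  West unweighted  1.648e-07 1.595e-07  1.669e-07 3.041e-01     113
```

The detection screen recovers 99.8% of the planted private alleles with
1.2% false seed calls. The ancient-cohort regression recovers the generating
East-Eurasian trend (the cohort was simulated with carrier probability
rising 1×10⁻⁵ per year BP: β_time ≈ 9.9×10⁻⁶, p ≈ 10⁻⁸¹) while the West
region, simulated flat, is correctly null (p = 0.30). The remaining drivers
(`analysis/02…07`) run the F_ST/NJ-tree, selection-scan, mutation-load and
pigmentation analyses the same way, each printing what it found and writing
its tables under `results/analysis/`.

A `basalkit` command-line entry point wraps the same library
(`basalkit run`, `simulate`, `fst`, `basn-detect`, `gs`, `scan`).

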