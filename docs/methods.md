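# Methods

This note documents the statistical procedures implemented in `basalkit`,
the synthetic-data models they are validated against, the defaults and why,
and the known limits of both.

## Statistical procedures

### Weir–Cockerham F_ST

Per-SNP variance components follow the 1984 estimator with samples taken at
the **haplotype level**: the data are phased, so each haplotype is a haploid
observation, the heterozygosity component vanishes (h̄ = 0, c = 0) and the
between/within components a and b carry the estimate. Genome-wide and
per-window values are the **ratio of sums** Σa / Σ(a+b+c) — the standard
recommendation for combining this estimator over loci — never the mean of
per-site ratios. Monomorphic sites contribute (0, 0). Per-site estimates may
be negative (finite-sample bias); they are truncated at zero only where a
downstream transform requires it (the sqrt-normalized gene scores, and the
pairwise distances fed to LSBL and the NJ tree).

Sliding windows (default 10 kb, step 1 kb) are anchored at multiples of the
step from position 0 of each chromosome; a site belongs to every window
whose span contains it. Per-gene values take the maximum F_ST over windows
overlapping the gene; gene scores are sqrt-transformed and z-scored across
genes, with outliers at z > 1.96 — the 1.96 cutoff strongly implies a
z-score reading of "normalized F_ST", which is the reading adopted here.
The population tree is neighbor joining (scikit-bio) on the pairwise
weighted-F_ST matrix, optionally rooted on an outgroup, with negative branch
lengths clamped to zero.

### bASN-derived allele detection

Stage 1 (seeds): derived allele frequency > 0.2 in ≥ 1 representative TIA
population **and** < 0.1 in every nonindigenous EUR/EAS reference
population; thresholds are strict inequalities. Stage 2 (linked): derived
alleles within 500 kb of a seed with r² > 0.5 to that seed, computed over
the **pooled haplotypes of the four representative TIA populations** — the
scope is a package choice (pooling maximizes power to tag bASN haplotypes)
and is configurable. Expansion is a single pass: linkage is to seeds only,
never transitively through linked alleles, which prevents runaway closure.
Unpolarized sites are skipped and counted. Block assignment is
single-linkage chaining: consecutive detected alleles ≤ 500 kb apart share
a block; a boundary requires a gap strictly greater than 500 kb.

### Genetic scores and the age regression

The presence indicator dᵢ is binary (≥ 1 derived allele observed), not a
dosage: ancient genotypes are pseudo-haploid, making presence the only
robust per-site observation. GS_unweighted averages dᵢ over the sample's
genotyped bASN sites; GS_weighted first averages within blocks, then over
blocks with ≥ 1 genotyped site (blocks with none are excluded from N).
When every block holds exactly one genotyped site the two scores coincide —
a property test enforces this.

The age regression is OLS of GS on sample age with latitude, longitude and
ten PC covariates. Samples whose genotyped-SNP count is **strictly below the
first quartile** (25th percentile, linear interpolation) of the cohort are
excluded before fitting. Both classical and HC1 heteroskedasticity-robust
standard errors are reported, since binomial GS noise scales with 1/m and m
varies across samples. A rank-deficient design raises an error naming the
collinear columns.

### Composite selection scan

EHH of a core-allele class at distance x is the fraction of haplotype pairs
in the class identical at every site from the core to x. iHH integrates EHH
against physical distance (trapezoid) outward in both directions, truncated
where EHH < 0.05; unstandardized iHS = ln(iHH_ancestral/iHH_derived) is
standardized to mean 0, SD 1 within 20 equal-width derived-frequency bins.
Sites are dropped (NaN) when minor allele frequency < 0.05, when either
allele class has < 2 haplotypes, when an inter-site gap exceeds 200 kb, or
when a chromosome edge is reached before truncation — the defaults of the
canonical iHS software, since no alternatives are specified; all are
configurable. Distances are physical bp: no genetic map is taken as input,
and this is the one deliberate deviation knob from map-based practice.

LSBL_focal = (d_FR + d_FO − d_RO)/2 on per-SNP pairwise F_ST with negative
inputs pre-truncated at zero. Empirical p-values are rank/n with rank 1 the
most extreme; ties share the smallest rank of their group; |iHS| is ranked
two-sided and LSBL upper-tail (selection pushes |iHS| and LSBL high by
construction; the sidedness is a package choice). F_CS = −log10 p_iHS −
log10 p_LSBL; a missing ingredient makes F_CS missing.

Outlier SNPs are the top 5% of F_CS genome-wide. Windows are non-overlapping
100 kb, discarded below 10 SNPs, binned into four SNP-count quartile groups,
and selected when their outlier-SNP proportion is in the top 5% of their
bin. All top-5% cuts use an inclusive threshold: ties at the boundary are
all selected, which is deterministic and errs toward inclusion.

### Mutation load

GERP bins are lower-exclusive/upper-inclusive — (2, 4], (4, 6], (6, ∞) — so
every score above 2 maps to exactly one bin; a score of exactly 4 or 6
belongs to the milder bin. Sites with GERP ≤ 2 (or no score) are excluded
from load entirely, including the genome-wide aggregate. The per-site load
is L = 2shf(1−f) + sf² on the derived allele frequency; with the default
additive dominance h = 0.5 this is algebraically s·f, and the implementation
satisfies the identity to 10⁻¹⁵ (tested on a grid). Aggregates report the
sum and the per-SNP mean over a site set, the mean being the cross-gene-set
comparable quantity.

### Pigmentation analyses

The polygenic score counts diploid copies (0/1/2) of the DPA effect allele
over the scored loci — "number of DPAs in an individual" is read as an
allele count, consistent with additive-model risk alleles. Putative DPAs are
alleles whose maximum frequency over the representative TIAs exceeds the
maximum over nonindigenous Eurasians; population-specific alleles are
present in ≥ 1 TIA population and absent from all nonindigenous Eurasians.
The African-sharing test is a two-sided Fisher's exact test on the 2×2 table
(pigmentary vs non-pigmentary population-specific alleles × present vs
absent in Africans); the odds ratio is the conditional maximum-likelihood
estimate (maximizing the Fisher noncentral hypergeometric likelihood, the
convention of R's `fisher.test`), not the sample cross-product ratio.

The AF-block screen implements three steps per population: count alleles at
frequency f (|AF − f| ≤ tol, default tol = 0.05 — exact equality is
meaningless on real frequencies) in non-overlapping 50-kb windows; keep
windows with ≥ 5 such alleles; merge adjacent kept windows and retain the
merged block containing the target variant. Blocks from multiple populations
are unioned. The network subsampler keeps populations of ≤ 50 whole,
downsamples larger ones to 50%, and always retains every carrier of the
target allele (carriers may exceed the cap); it is deterministic per seed.

## Synthetic-data models

**Structured frequencies (Balding–Nichols).** Each population's allele
frequency at a background site is Beta-distributed around a shared ancestral
frequency p ~ U(0.05, 0.95) with drift parameter F; genotypes are binomial
draws. bASN-private sites have frequency zero outside the basal lineage and
α_k·q in population k, where q ~ U(0.8, 1.0) is the allele's frequency on
the basal lineage itself — private variants of a deeply diverged lineage
are old and hence common within it, which is what makes a frequency screen
at 0.2 able to find them at α = 0.3. Defaults: six populations (four TIA at
α = 0.3, EUR/EAS at α = 0), 50 samples each, F = 0.02 (within-region
human-scale drift), 2,000 background + 500 private sites, 10-kb spacing.
Sites are unlinked: this generator feeds frequency-based statistics only.

**Sweep haplotypes.** Haplotypes are mosaics of 30 founder haplotypes with
per-site template-switch probability r·gap; r is a population-scale
haplotype-shuffling rate (default 10⁻⁵/bp), chosen so pairwise haplotype
identity decays over tens of kb as in human data — it is not a per-meiosis
crossover rate. Sweep carriers (closest count to the target frequency)
share one core haplotype over the configured core length and escape it at
exponential distances (rate r) beyond the core edges; with r = 0 carriers
are identical over the whole span. The derived allele at the selected site
is carried by exactly the carriers. Defaults: 200 haplotypes, 1,500 sites
over 3 Mb, final frequency 0.5, 200-kb core. A companion helper drifts
reference and outgroup allele frequencies (Balding–Nichols, F = 0.02 and
0.1) from the focal background so that the sweep also lifts LSBL.

**Ancient cohort.** Pseudo-haploid calls (derived/ancestral/missing) at the
supplied bASN sites; a sample's carrier probability is base + slope·age,
clipped to [0, 1], with region-specific slope (default: East 10⁻⁵ per year
BP, West 0, base 0.2 — a moderate trend from 0.2 to 0.7 over the 0–50 ka
range). Per-sample missingness is uniform on [0, 0.6] so genotyped-SNP
counts vary and the first-quartile filter has bite. Latitude, longitude and
PCs are generated with zero true effect.

**What the generators do not emulate** — and hence what passing tests do not
show about real data: coalescent genealogies and realistic site-frequency
spectra; LD between the unlinked frequency-simulated sites (detection
stage 2 is therefore exercised mainly by the haplotype generator and by
construction tests); archaic introgression; aDNA damage and reference bias;
non-uniform sampling of ancient dates and locations; selection acting on
standing variation rather than a planted identical core. Recovery rates
measured here (detection recall, sweep localization, regression calibration)
are under these idealized conditions.

## Problem sizes and numerical choices

Validation workloads are sized for a single CPU: F_ST recovery uses
2 populations × 50 samples × 2,000 sites × 20 replicates per drift level;
detection recovery one cohort of 2,500 sites; sweep localization 20
replicates of 1,500 sites; the neutral window calibration one genome of
100,000 sites in 2,000 100-kb windows; regression calibration 2 × 50
cohorts of 200 samples. The iHS inner loop is numba-compiled; its
correctness is pinned to an O(n²) pair-enumeration oracle, exactly, in the
test suite. Empirical-p ties share the minimum rank; quantile cuts include
boundary ties; the first quartile uses numpy's linear-interpolation
definition; percentages in region reports are rounded half-up to one
decimal. Degenerate inputs raise rather than guess: samples with zero
genotyped bASN sites have undefined GS, empty eligible load sets raise, and
unphased, multiallelic or missing modern genotypes are rejected at read
time (the study design assumes phased, imputed modern sequences; ancient
missingness is explicit instead).

## Known limitations

Windows are anchored at coordinate 0 rather than data-driven breakpoints;
iHS uses physical distance; the LD scope and the empirical-p sidedness are
conventions that real reanalyses may need to vary (both are parameters);
the conditional-MLE odds ratio is undefined (0 or ∞) for tables with an
empty diagonal, as in R. The bundled top-region table is a curated summary
for bookkeeping checks, not a dataset on which the detection pipeline can
be rerun.
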