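# Methods

## Data model and coordinates

Genotypes are held as a sites × samples matrix of diploid allele dosages
(0, 1, 2, missing) with per-site contig/position/allele metadata and
optional GATK-style site annotations (QD, FS, MQ, MQRankSum,
ReadPosRankSum) and genotype annotations (GQ, DP). VCF input/output is
1-based; all internal interval arithmetic (windows, genes, islands, BED)
is 0-based half-open, so a VCF position `p` lies in window `[s, e)` iff
`s ≤ p−1 < e`. GFF3 gene features are converted from 1-based closed on
input and restored on output; round trips are lossless.

## SNP filtering cascade

Filters run in a fixed order: (1) site-level hard filters on INFO
annotations (QD < 2, FS > 60, MQ < 40, MQRankSum < −12.5,
ReadPosRankSum < −8 remove the site; a missing annotation skips that
criterion rather than failing it, since not every VCF carries GATK
annotations); (2) removal of sites within 5 bp of a supplied indel
position; (3) genotype-level masking — GQ < 30, or DP outside the
2.5–97.5 percentile band of the pooled genome-wide per-genotype depth
distribution (linear interpolation, computed once per dataset) — sets
individual genotypes to missing; (4) non-biallelic sites removed;
(5) call rate ≥ 80% of individuals; (6) folded minor allele frequency
≥ 0.05 among called alleles (both thresholds inclusive). Masking precedes
the frequency criteria so MAF and call rate describe the genotypes
actually retained. Call rate and MAF are evaluated pooled across all
analysed samples by default; a per-species mode requires each species to
pass separately. Samples flagged as excluded (e.g. admixed individuals)
contribute to nothing downstream.

Masked genotypes keep their recorded DP so the depth band does not drift
when the cascade is re-applied; with a stable band the cascade is
idempotent.

## Windowed statistics

All estimators use per-site called-allele counts; no imputation. Per-bp
statistics divide by the full window length (sites absent from the
filtered matrix are assumed invariant); an accessible-sites denominator is
available where that assumption is unsafe. Hudson's F_ST is accumulated as
per-SNP numerator/denominator pairs

    num = (p_A − p_B)² − p_A(1−p_A)/(n_A−1) − p_B(1−p_B)/(n_B−1)
    den = p_A(1−p_B) + p_B(1−p_A)

with a window's value the ratio of sums — this makes windows with few
SNPs well-behaved and lets the permutation null resample the identical
decomposition. Sites where either population has fewer than two called
alleles are skipped. Negative window values are retained (they are
informative noise around zero), and clamped to [0, 1−10⁻⁶] only at the
PBS log transform. Weir–Cockerham (1984) two-population components are
offered behind `estimator="wc"`; Hudson is the default because it is
robust to unequal sample sizes and decomposes per SNP.

Tajima's D uses the standard 1989 constants with the sample size set to
the modal called-allele count over the window's sites; sites whose call
count deviates from the mode by more than 20% are excluded from D only.
D is undefined for S = 0 or n < 4. LD decay reports the mean squared
Pearson correlation of unphased dosage vectors over co-called samples,
binned by pair distance; species can be subsampled to a common size
(seeded) for comparability.

Window sizes are fully configurable; the pipeline defaults to 20 kb for
the diversity table and 50 kb for the island scan, the two sizes most
natural for these respective uses.

## Island detection

Per species pair, windows are grouped into SNP-count categories (exact
count up to 50, power-of-two bins above). For each category, B
pseudo-windows are built by drawing that many per-SNP component pairs
jointly, uniformly *without replacement within a draw*, from the
genome-wide pool; each draw's F_ST is again a ratio of sums, so the null
is a distribution of valid estimator values conditioned on information
content. The empirical p-value uses the add-one rule
p = (1 + #{null ≥ obs})/(1 + B), never zero, so BH correction is always
defined. Outliers must be in the top 5% of the observed distribution
*and* have q < 0.01; adjacent outliers merge (configurable window gap;
overlapping sliding windows merge by union). Undefined-F_ST windows are
excluded and counted.

B defaults to 1000. Note a resolution constraint: with n windows of which
k are true outliers, the smallest attainable q is n/(k(B+1)), so detecting
a small number of true windows at q < 0.01 needs B on the order of
100·n/k. The acceptance analyses on ~200-window genomes therefore use
B = 10 000.

Island-vs-background contrasts (π, Tajima's D, D_xy, LD, optional
external per-window recombination track) use two-sided Mann–Whitney U
with the direction reported as the sign of the median difference; groups
smaller than 3 windows are undefined.

## Selection scan

S counts sites polymorphic within the focal species; D counts reciprocal
fixation — focal fixed for one allele and (default "pooled" mode) both
other species fixed for the alternative; a "pairwise-sum" mode instead
sums reciprocally fixed sites over the two focal-vs-other comparisons.
Fixation requires a per-species call rate ≥ 0.8 at the site and frequency
exactly 0 or 1 among called alleles — no tolerance, matching the strict
reciprocal-fixation definition. The HKA test is implemented as a 2×2
contingency comparison of the gene's (S, D) against the rest of the
genome (all genes summed), Pearson chi-square with df = 1 or Fisher's
exact test when any expected cell is below 5; this matches the
"gene vs genome-wide expectation" formulation rather than the original
multi-locus variance-weighted HKA. No directionality filter is applied to
HKA; the PBS top-fraction requirement enforces the divergence-excess
direction implicitly.

Gene-level F_ST is the component ratio over the gene's SNPs (not an
average of overlapping window values), and PBS is computed from the three
pairwise values. PSG calling applies BH within each focal species' gene
list and a per-species PBS quantile cutoff; both thresholds (q < 0.01,
top 5%) are parameters. Genes with fewer than 3 sites are flagged
low-information. The sharing summary treats each species' PSG set as an
independent uniform draw of its size from the gene universe: per-gene
inclusion probabilities k_i/N give the expected shared-by-≥2 and unique
counts by inclusion–exclusion, compared to observation with a chi-square
over the (≥2, exactly 1, 0)-species categories. The gene universe is a
parameter (the pipeline uses all annotated genes).

## Synthetic data generator

The generator emulates a strongly differentiated three-species radiation
on the fixed topology ((OK, OI), OT) at desk scale. Per SNP: ancestral
frequency p₀ ~ U(0.05, 0.95); Balding–Nichols drift
p' ~ Beta(p(1−F)/F, (1−p)(1−F)/F) along the internal branch (F_anc) and
each tip branch (F_OT, F_OK, F_OI); one-shot directed migration
admixture p_i ← (1−Σm)p_i + Σ m·p_j on post-drift frequencies;
genotypes Binomial(2, p) per individual with 2% missingness. Under this
model the expected Hudson F_ST of a pair is half the sum of the two tips'
compound drift variance factors (1 − Π(1−F) from root to tip — the
shared ancestral branch cancels), slightly shrunk by migration. The
defaults (F_OT = 0.50, F_anc = 0.20, F_OK = 0.46, F_OI = 0.36; migration
0.02 between OT and each of OK/OI, 0.005 between OK and OI) put the
pairs near 0.49/0.45/0.38 with the deepest OT split the strongest and
gene flow strongest involving OT — the regime the scan statistics are
designed for. Default sample sizes are 18/15/9 (a 54:45:27 ratio at
one-third scale); default SNP density 1/200 bp.

Because continuous frequency drift alone almost never yields *exactly*
fixed samples at desk scale, a configurable fraction of sites (default
2%) are lineage-sorting sites: one tip branch starts near one allele
boundary and the rest of the tree near the other, producing the
reciprocally fixed differences that deep divergence supplies in real
data. Planted structure with recorded truth: islands (intervals whose
branch drift is multiplied by λ, capped below 1; optionally with an
elevated sorting rate to plant ancestral divergence that raises D_xy),
and sweep genes (focal frequency pushed toward the nearer boundary with
strength s, residual focal polymorphism thinned, and a boosted sorting
rate on the focal branch — jointly the S-deficit + D-excess + long-PBS
signature that HKA/PBS target).

What the generator does *not* emulate: linkage (sites are exchangeable
given their frequency history; LD tests use explicitly planted correlated
blocks that copy a template dosage column with noise), recombination-rate
variation, explicit Wright–Fisher sweep dynamics, mutation-model detail,
or GATK annotation distributions (synthetic VCFs carry GT only, which the
filter cascade tolerates). Passing recovery tests therefore demonstrates
the correctness and calibration of the scan machinery under the assumed
frequency model, not performance on linked, annotation-rich real data.

## Pipeline and reproducibility

`run_pipeline` executes filter → stats → islands → select into a run
directory, committing each stage's outputs atomically (failures leave
`.partial` files) and writing a manifest with input SHA-256 checksums,
the resolved configuration, package/library versions, and per-stage child
seeds derived from the single run seed by stable CRC-32 hashing of the
stage name (always < 2³¹), so stages re-run independently with identical
results. All outputs are deterministic given (inputs, config, seed);
identical seeds give byte-identical island BED and PSG tables.

## Problem sizes

The bundled analyses use desk-scale genomes chosen to make every property
measurable with comfortable statistical resolution: 1–10 Mb contigs,
5 000–80 000 SNPs, 42 samples. Calibration checks use a no-structure
configuration (all F = 10⁻⁴, no migration, no sorting sites) with 400
windows and B = 500; island recovery plants λ = 5 islands on 2% of a
10 Mb genome (3 replicates, B = 10 000); sweep recovery uses 20
replicates of a 5 Mb genome with one sweep per species.

## Known limitations

- The permutation null treats SNPs as exchangeable genome-wide; under
  strong local autocorrelation of components (real linkage) it is
  anti-conservative in a way the simulator, being linkage-free, cannot
  expose.
- The contingency HKA lacks the variance weighting of the original test
  and treats genes as independent of the genome-wide total (the gene is
  subtracted from the margin, so overlap bias is avoided, but genes are
  not independent of each other).
- One-shot migration is a crude stand-in for continuous gene flow; it
  rescales differentiation but cannot generate the length-biased
  introgression tracts real secondary contact leaves.
- Sample-fixation-based D counts are sensitive to sample size; with very
  small per-species n, polymorphic sites can appear fixed and inflate D.
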