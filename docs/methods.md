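# Methods

This note documents the models, conventions and design choices behind
`buffroh`, in the spirit of the methods documentation that simulation and
statistics packages in this field ship with their code.

## Data model and quality control

Genotypes are held as an `int8` allele-B dosage matrix (individuals × SNPs,
−1 = missing) with a sorted SNP map (chromosomes 1–24 only; sex chromosomes
and unplaced scaffolds are dropped on read) and a sample sheet giving buffalo
type (river/swamp) and breed/population. PLINK text `.ped/.map` is the
exchange format; allele "0" is missing, and per SNP the two alleles are the
lexicographically sorted observed letters (a monomorphic SNP codes as dosage
0 of an unobserved second allele, so allele labels are not preserved for
columns where only one allele is seen).

QC runs as a cascade, in this order: animals with call rate < 0.95 are
removed first; then SNPs with call rate < 0.95, then SNPs with MAF < 0.01.
Call rate is the fraction of non-missing calls; MAF is computed from
non-missing calls only. Re-running the cascade on its own output is a no-op.

Three datasets are built from the jointly QC'd panel:

- **ALL_DATA** — all animals, restricted to SNPs with both alleles observed
  among the swamp animals (MAF > 0 within swamp, not a 1% threshold). This
  counters the river-ascertained array's bias in joint comparisons.
- **RIVER_DATA / SWAMP_DATA** — one type's animals with call-rate and MAF
  pruning re-applied within type, plus a Hardy–Weinberg exact-test filter at
  P < 1e-5. The HWE test is the two-sided conditional exact test: summing,
  over all heterozygote counts compatible with the observed allele counts,
  the probabilities not exceeding that of the observed configuration
  (computed in log space; ties matched with 1e-12 relative slack). ALL_DATA
  receives no HWE filter.

The initial MAF filter uses all animals jointly; the within-type filters then
handle type-specific frequencies.

## ROH detection

A ROH is a maximal run of consecutive map SNPs for one animal that is
homozygous and called throughout, split wherever the distance between two
consecutive SNPs exceeds `max_gap_bp`, then filtered to `min_snps` ≥ 15 and
`length_bp` ≥ 1 Mb (defaults; all four limits configurable). Conventions:

- `length_bp = end_bp − start_bp` (not +1), so a run spanning exactly 1 Mb
  meets the threshold; the same convention is used everywhere downstream.
- A gap above the budget terminates a run even between two homozygous calls.
- Missing calls terminate runs by default (`max_missing = 0`); the
  `max_het`/`max_missing` budgets support the more permissive settings used
  in some of the buffalo literature. With nonzero budgets, runs are the
  maximal windows within budget, trimmed to homozygous endpoints, found by a
  monotone two-pointer sweep; with zero budgets a vectorized run-length scan
  is used. Both paths are checked in tests against an oracle that enumerates
  every window and verifies all four criteria plus maximality.

## ROH summaries

F_ROH(t) is the summed length of an animal's ROH longer than t, divided by
the genome length, with t ∈ {0, 2, 4, 8} Mb (strict "longer than"). The
default denominator is the map span — Σ over chromosomes of (last − first
mapped position) — because it is reproducible from the input alone; an
assembly length can be passed instead. Length classes are upper-inclusive
(1–2, 2–4, 4–8, 8–16, > 16 Mb); a run of exactly 1 Mb (the detection floor)
belongs to the first class. Unique ROH are distinct
(chromosome, start, end) signatures; the carrier table records which animals
and populations share each signature. Within-ROH SNP spacing is
length/(n_snps − 1), averaged per length class.

## Island scan

SNP_ROH counts, per SNP, the animals with a ROH whose inclusive span contains
the SNP. By construction Σ over SNPs of SNP_ROH equals Σ over ROH of n_snps,
which tests use as an exact conservation check. Significance uses the
nearest-rank empirical 99th percentile over all SNPs (zeros included), with a
strict ">" so a flat track flags nothing and large tie groups are not swept
in. Islands chain significant SNPs on a chromosome while consecutive members
are ≤ 1 Mb apart and keep chains of ≥ 2 SNPs; these two constants are read
off the smallest island and the island-exclusion rule reported for this kind
of scan and are configurable. Whether zero-count SNPs enter the percentile is
debatable; we include all dataset SNPs.

## G_ROH: ROH-coded relationship matrix

Genotypes are recoded per animal: 0 = heterozygous, 1 = homozygous outside,
2 = homozygous inside one of that animal's ROH longer than 4 Mb (threshold
configurable; missing stays missing). The relationship matrix follows
VanRaden's first method applied to the coded matrix: column frequencies
pᵢ = mean(code)/2 over non-missing entries, Z = code − 2pᵢ with missing
entries zeroed after centring (the standard GRM practice), degenerate columns
(pᵢ ∈ {0,1}) excluded from numerator and denominator, and
G = ZZ′ / (2 Σ pᵢ(1−pᵢ)). Frequencies come from the coded matrix itself, not
from the raw genotypes — the recoding is the point of the matrix — and this
choice is isolated in one function if a different scaling is wanted.
Eigen-decomposition uses the full symmetric solver on the n × n matrix;
eigenvalues are sorted descending, percent variance is eigenvalue/trace, and
each eigenvector's largest-magnitude coefficient is made positive so signs
are reproducible. Per-population and per-type means of the leading
eigenvectors are reported for structure plots.

## Differentiation scans

F_ST uses the two-population Wright/Nei form on unweighted group frequencies:
H_S = (2p₁q₁ + 2p₂q₂)/2, H_T = 2p̄q̄, F_ST = (H_T − H_S)/H_T, defined as 0
when H_T = 0. This estimator is symmetric in the group labels and bounded in
[0,1]. A Weir–Cockerham estimator with sample-size weighting is available as
an alternative (`estimator="weir_cockerham"`).

Smoothing is classic LOWESS per chromosome: tricube-weighted local linear
regression over the k nearest neighbours (k = round(span × n), default span
0.05 — no span is standard for this scan, so it is configurable) with three
bisquare robustifying passes. The implementation is in-package so the
windowing and weighting conventions are pinned and testable to 1e-8 against
a brute-force reference; it reproduces constants and straight lines exactly,
and agrees closely with the statsmodels implementation on smooth tracks.
Chromosomes with fewer than three informative SNPs pass through unchanged.
Outliers are SNPs whose smoothed value lies strictly above mean + 3 sample
SD of the smoothed track (one-sided: only high differentiation is of
interest).

The logistic scan fits, per SNP, log(p/(1−p)) = β₀ + β_type for the
per-animal in-ROH indicator with river as the reference level, by Newton
iterations on the aggregated two-row binomial likelihood (vectorized over
SNPs; convergence 1e-10 on deviance, max 50 iterations). With a single
binary covariate the MLE odds ratio equals the 2×2 cross-product ratio,
which tests exploit as an oracle. A SNP with an empty cell (a type entirely
in or out of ROH) is flagged as separated, its odds ratio reported as 0/∞,
and no Wald P-value computed; separated SNPs are excluded from odds-ratio
averages and their count is reported.

## Synthetic data

The generator plants truth rather than simulating ancestry: coalescent or
recombination-explicit simulation is a non-goal because detection tests need
exact segment boundaries. Its defaults are the study conditions:

- 24 autosomes of 100 Mb at 2,000 SNPs each (~1 SNP / 50 kb, ≈ 48 K markers
  over 2.4 Gb, the scale on which the 15-SNP/1-Mb criteria are comparably
  binding); positions uniform, ancestral allele-B frequencies U(0.05, 0.5).
- The study roster: 185 river animals in 15 breeds and 153 swamp animals in
  13 populations, each population drifting (Balding–Nichols beta) around its
  type frequency with F_drift = 0.05.
- Ascertainment bias: 60% of SNPs forced monomorphic in swamp, emulating a
  river-designed array that detects only about one-third of its SNPs in
  swamp. Type-level divergence is asymmetric — river F = 0.05 (close to the
  ascertainment pool), swamp F = 0.25 at the SNPs that stay polymorphic.
  With these defaults the realized between-type mean F_ST is ≈ 0.1; pushing
  the swamp divergence to ≈ 0.75 instead reproduces a mean F_ST of ≈ 0.2 on
  swamp-polymorphic SNPs, but at the cost of extreme within-swamp
  frequencies that roughly triple the background ROH count. Since the ROH
  statistics are the primary quantities here, the defaults favour the
  ROH-side realism and the F_ST-targeting configuration is exercised
  explicitly in tests.
- Autozygosity: per animal a Poisson number of segments (mean 40 river, 70
  swamp — the joint-analysis per-animal ROH counts), with lengths
  1 Mb + a mixture of exponentials (75% mean 1.2 Mb, 25% mean 5 Mb; overall
  mean ≈ 3.2 Mb, matching the observed length scale). Within a segment every
  SNP is set homozygous for an allele drawn by frequency. Island loci
  (default: seven shared hotspots, swamp-skewed) add boosted-probability
  segments covering fixed positions.
- Boundary realism: by default the SNP immediately flanking each planted
  segment is set heterozygous where the population frequency allows
  (`crisp_boundaries`), so planted boundaries are identifiable to one
  inter-SNP interval; where a flank is monomorphic no heterozygote can
  exist and detected runs may extend — exactly as in real data.
- Missingness: 0.2% at random, a typical post-sample-QC array rate.

What the generator does *not* emulate: linkage disequilibrium and realistic
local recombination structure, mutation, chromosome-length variation, and
genuine identity-by-descent sharing between relatives. Passing tests
therefore show that the pipeline's rules and algebra are correct under the
assumed frequency-and-segment model, not that the biological interpretation
of any real dataset is right.

Recovery scoring: a planted segment is *expected recoverable* when the SNPs
it spans on the analysis map meet all four detection criteria as realized in
the genotypes (a random missing call inside the segment disqualifies it
under the no-missing rule). It counts as recovered when detected segments of
the same animal overlap it with both boundaries within one inter-SNP
interval (or an explicit tolerance). Detected segments overlapping no
planted segment are counted as false discoveries — on realistic panels these
are genuine background homozygosity runs, not errors, and they are reported
rather than suppressed.

## Problem sizes

The default test-suite panels use 4–6 chromosomes with 800–2,000 SNPs each
and 24–60 animals; the analysis drivers and the acceptance script run the
full 338-animal × 48 K-SNP study scale, which completes in well under a
minute end to end on one CPU. Detection-oracle equivalence is checked on 200
random 500-SNP chromosomes against exhaustive window enumeration.

## Known limitations

- PLINK binary (`.bed`) input is not supported; text `.ped/.map` only.
- The lognormal mixed-model analysis of ROH length/count (type, breed and
  chromosome effects with an animal random effect) and gene-annotation
  lookups for islands are out of scope.
- The F_ST estimator pair (Nei-style default, Weir–Cockerham option) does
  not include permutation-based significance; outliers are threshold-based.
- Allele labels are not round-tripped for monomorphic SNPs (see above).
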