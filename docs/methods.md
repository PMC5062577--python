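# Methods

## The statistic

For a gene with K predicted-KO individuals out of N phenotyped samples, the
test statistic is the mean normalized phenotype *m* of the KO group. The
null distribution is generated by permutation: each replicate draws K
phenotypes without replacement from the full vector (equivalently, permutes
phenotype labels) and records its mean *mᵢ*. With *n* permutations,

    P_left  = #{mᵢ ≤ m} / n
    P_right = #{mᵢ ≥ m} / n
    P_final = min(1, 2 · min(P_left, P_right))

Ties count on both sides, which makes the test conservative rather than
anti-conservative on discrete phenotypes. The two-sided doubling can exceed
1 (e.g. when *m* sits at the distribution's center), so P_final is capped;
the cap only ever activates for unremarkable genes. A zero count is reported
as P = 0 together with *n* — the resolution floor is 1/n, and the adaptive
escalation (below) is what refines it. No +1 pseudo-count is applied: the
reported value is the plain empirical tail frequency, and P_left alone is
uniform on the grid {0, 1/n, …, 1} under the null.

Assumptions: individuals are unrelated; the normalized phenotype is
symmetric (guaranteed in practice by the inverse normal transform); all LoF
alleles of a gene shift the mean in the same direction. Phenotypic-variance
effects are out of scope.

### Scan orchestration

Every gene with at least `min_n_ko` phenotyped KO individuals is tested with
10,000 permutations; genes with P_final < 2×10⁻⁴ are re-run with 100,000
permutations and the escalated result replaces the first. The escalation
criterion is P_final by default; `escalate_on="onesided"` compares
min(P_left, P_right) instead, preserving both readings of "empirical P".
Per-gene RNG streams derive deterministically from (run seed, gene id,
stage), so results are independent of gene order and reproducible under
parallelization. The genome-wide significance default is α = 2×10⁻⁵
(Bonferroni for the ~2,500 genes with ≥ 1 KO in a sequencing-scale cohort).
λ_GC is the median 1-df χ² quantile of the P values over 0.4549; for λ and
QQ tables, exact zeros are floored at half the permutation resolution
(0.5/n) since −log₁₀ 0 is unusable for plotting.

## KO definitions

* **homozygous** — both alleles ALT at one LoF site.
* **compound heterozygous** — ≥ 2 distinct heterozygous LoF sites in trans.
  With phased genotypes, trans means ALT alleles on opposite haplotypes and
  a cis-only pair is *not* a KO. Without phase (`assume_trans_if_rare`), any
  two rare heterozygous LoF sites qualify — the standard exome-array
  convention; on phased data this policy therefore calls a superset of the
  phased calls. With ≥ 3 het sites, any qualifying pair suffices.
* **hemizygous** — a male with a single LoF allele at an X site outside the
  pseudoautosomal regions (GRCh37 PAR coordinates ship with the package;
  assembly-dependent, override with `--par-bed`). A heterozygous male call
  at X non-PAR is a caller artifact; the default policy counts it as one
  LoF allele (with a warning), `--x-het-policy missing` ignores it.

Missing genotypes contribute nothing and leave the individual eligible as
non-KO. A variant only counts for samples whose stratum it passed QC in.
"Rare" for the trans assumption reuses the inclusion threshold (MAF < 5%).

## Annotation and QC

Classification is per transcript; gene-level aggregation defaults to the
most severe class over transcripts (`any`), with an `all` mode (LoF only if
every transcript is hit) for annotation-sensitivity analyses. Severity order
is nonsense > frameshift > splice_site > stop_loss. When a variant qualifies
as both a coding consequence and a splice-window hit (possible under
`flank2`), the coding consequence wins — exactly one class per
(variant, transcript). Frameshift calling is the |inserted − deleted| mod 3
rule on CDS-overlapping indels; no downstream stop-scanning, no NMD-escape
or 3'-rescue modeling, and missense variants are entirely out of scope.
Splice windows attach only to internal exon boundaries (transcript ends do
not splice): `intronic2` is the two intronic bases at each junction,
`flank2` adds the two exonic bases, strictly containing the former.

QC is per stratum: call rate ≥ 95%, exact conditional Hardy–Weinberg test
(no mid-p; haploid X calls excluded from the HWE genotype counts) at
P ≥ 10⁻⁶ (a 10⁻⁸ profile suits low-pass WGS), and folded MAF in (0, 5%)
computed over called alleles only. The HWE filter is applied per stratum by
default (`hwe_pooled` pools it); the tests verify the exact test against
full enumeration of the conditional null.

Transcripts whose CDS length is not a positive multiple of 3 are excluded
with a warning. Internally all intervals are 0-based half-open; VCF (1-based)
and GFF3 (1-based inclusive) are converted at the boundary. Multi-allelic
VCF records are split per ALT before annotation, so a sample heterozygous
for two ALT alleles at one site carries two distinct candidate LoF alleles.
Gene identity across VCF, gene models and gene-set files is plain string
match — no alias database.

## Phenotype normalization

Per stratum: listwise deletion of missing values, OLS residualization on the
configured covariates (an intercept is always added; rank-deficient designs
fail naming the collinear columns), then the rank-based inverse normal
transform z = Φ⁻¹((r − ½)/n) with average ranks for ties. The (r − ½)/n
offset (no Blom constant) is a declared convention: simple, symmetric, and
immaterial to permutation inference, which is rank-based either way.
Trait-specific exclusions (e.g. implausible BMI) are a configurable
pre-filter utility, not hard-coded science.

## Meta-analysis and effect display

Two weightings serve two purposes. The combined **P** follows the
sample-size weighted Z-score scheme: Zᵢ = Φ⁻¹(1 − Pᵢ/2) · sign(mᵢ),
Z = Σ Zᵢ√Nᵢ / √ΣNᵢ, P = 2(1 − Φ(|Z|)). A study P of exactly 0 cannot be
converted to a Z score and raises an error directing the user to escalate
permutations or set a floor (the pipeline floors at 1/n). The combined
**effect display** is the N_KO-weighted mean of per-study KO means in SD
units; the metric-unit column multiplies the display-rounded (one decimal,
half away from zero) SD value by a per-trait conversion factor (e.g.
4.5 kg/m² per SD for BMI) — this is the arithmetic that keeps the SD and
metric columns of a report mutually consistent; full-precision values are
emitted alongside. Note the √N weighting is deliberately not additive under
splitting a study in two — a property of the scheme, asserted in tests.

Candidate-gene enrichment is a two-sided Fisher exact test on the 2×2 table
{in set, not in set} × {P_final < 0.05, ≥ 0.05} over tested genes, reported
raw (no correction across sets), with degenerate tables flagged (OR
undefined, P = 1). Stratified QQ overlays reuse the order-statistic band:
the i-th of n uniforms is Beta(i, n − i + 1), plotted at its 2.5/97.5
percentiles on the −log₁₀ scale.

## Power model

One recessive variant per replicate: genotypes at Hardy–Weinberg frequencies
((1−q)², 2q(1−q), q²), homozygote effect β = √(h²/(p(1−p))) with p = q² on a
standard-normal noise background, so the homozygote indicator explains a
fraction h² of the phenotypic variance of the standardized trait. "Variance
explained" is interpreted on the phenotypic scale — the standard convention
in power work; definitions based on the additive genetic variance of a
recessive locus would give a much smaller allelic substitution effect. The
phenotype is INT-transformed within each replicate before testing, mirroring
the real pipeline.

Inside the simulator the permutation null is replaced by its exact
finite-population normal approximation: under sampling K of N values without
replacement the KO-group mean has variance (s²/K)·(N−K)/(N−1) around the
grand mean. Running 5,000 × 10⁵ permutations would be wasteful; the
approximation is validated against the real permutation engine across the
relevant p range in the test suite. Replicates with zero homozygotes count
as non-detections. The additive comparator regresses the INT phenotype on
allele dosage with a two-sided Wald test. At the reference scenario
(q = 0.05, h² = 1%, N = 4500, α = 2×10⁻⁵) the KO-mean test attains ~95%
power and the additive test a few percent — the recessive signal is nearly
invisible to additive single-variant testing.

## Synthetic cohorts

The generator's defaults describe the emulated study conditions: a
sequencing-cohort stratum of a few thousand samples; genes of four 40-codon
exons with generated CDS sequences (stop-free except the terminal TAA, so
the annotator reads real codons); 2–3 rare LoF sites per gene with
per-stratum MAF uniform on (0.005, 0.045), safely inside the 5% inclusion
bound; a BMI-like raw trait (intercept 27, noise SD 4.5) with sex, age and
PC covariate structure. Haplotypes are drawn independently per site at the
stratum allele frequency, so genotypes satisfy Hardy–Weinberg in expectation
and compound-het pairs land in cis or trans with equal probability unless a
`cis_fraction` (or a forced-cis gene, for phasing tests) overrides the
arrangement — rearrangement only ever permutes the two haplotypes of het
calls, leaving genotypes untouched. Planted KO effects are applied on the
raw-trait scale (effect in SD units × noise SD) to individuals whose
realized genotypes constitute a KO under the trans rule, so residualization
and INT are exercised end to end; the truth ledger records every planted KO
with its mechanism, including non-KO cis pairs. Identical config + seed
reproduces byte-identical files.

Not modeled: linkage disequilibrium, genotyping/sequencing error, coverage
heterogeneity, relatedness, admixture beyond stratum allele frequencies.
Passing tests on these cohorts therefore validate the statistical machinery
and bookkeeping, not robustness to real-data artifacts.

## Problem sizes and numerical choices

The test suite's calibration check uses a null cohort of 800 genes × 2,500
samples (≈ 2,400 variants) — the smallest scale at which the 95% binomial
band around 0.05 and the λ_GC ∈ [0.9, 1.1] window are meaningfully tight —
and the recovery check uses 20 seeded runs of 5,000 samples with a planted
2-SD gene (two sites at MAF 3.5–4.5%, ≥ 12 expected KOs). The power study
uses the full 5,000 replicates per scenario. Permutation subsets are drawn
by duplicate-rejection when K(K−1) < N and by partial argsort of random
keys otherwise; both are exactly uniform over K-subsets. Exhaustive
enumeration is available for small cohorts (C(N, K) ≤ 5×10⁶) and matches an
independent combinatorial oracle exactly. Empirical-P comparisons use plain
≤/≥ on floating-point means: exact ties arise from identical subsets or
discrete phenotypes and are deliberately counted on both sides.

## Known limitations

* Unphased `use_phase` data contributes no compound hets (only phased pairs
  can establish trans); mixed phasing is handled pairwise.
* The permutation P is granular below 1/n even after escalation; downstream
  meta-analysis requires a floor for zero Ps.
* Fisher enrichment and the scan treat genes as independent; overlapping
  genes (shared variants) mildly violate this.
* The power simulator models a single variant per gene and ignores
  additional LoF alleles that the full method would aggregate, so it
  understates the gene-level test's advantage.
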