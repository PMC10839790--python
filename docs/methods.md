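# Methods

This note documents the models and procedures `hlakit` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Allele nomenclature

All comparisons happen at two-field ("4-digit", protein-level) resolution:
`LOCUS*field1:field2` with an optional expression suffix (N/L/S/Q).
Higher-resolution fields on input are truncated with a log notice.
Expression suffixes are preserved in storage but ignored in matching by
default, because the sequencing-based typing tools integrated here cannot
discriminate, e.g., a null allele like DRB4\*01:03N from \*01:03. G groups
(alleles identical across the exons encoding the peptide-binding domains)
are a user-supplied partition table; alleles absent from it are singleton
groups, so the partition property holds for any input. The bundled
`g_groups.tsv` is a small illustrative fixture, not an IMGT/HLA import.

## Consensus genotyping

Candidates are whole unordered allele pairs, not per-allele votes: the
agreement rule is phrased over the genotype a caller reports, and
genotype-level matching is what makes a single discordant allele break
support. A caller reporting one allele is stored as a putative homozygote
and supports only the homozygous candidate — single-allele detection is
treated as homozygosity, as is conventional when pedigree or SNP data to
exclude uniparental isodisomy are unavailable. A candidate qualifies when
its supporters span ≥ 2 distinct algorithms AND ≥ 2 distinct sample
identifiers (materials are logged but not constrained: two WES samples
count). Stage 1 restricts the algorithm set to the two primary callers
(HLA-HD, HLAProfiler); stage 2 opens the fallback set. If several
candidates qualify simultaneously the locus is reported unresolved with
all candidates listed; there is no frequency-based tie-breaking, because
the consensus rule is deliberately evidence-only. Completeness is counted
over the eight classical loci.

## Haplotype inference

**Enumeration.** A genotype with H heterozygous loci is compatible with
exactly 2^(H−1) unordered haplotype pairs; enumeration is exhaustive with
deduplication on the unordered pair key. This is exact, not sampled, which
bounds practical use to the locus counts used here (3-locus blocks; ≤ 2^10
pairs are instantaneous).

**EM.** Standard EM for haplotype frequencies from unphased genotypes
under random mating. E-step: pair (h₁,h₂) of individual i gets weight
f(h₁)f(h₂)·(2 if h₁≠h₂), normalized within the individual. M-step:
f(h) = expected count / 2N. Initialization is uniform over the haplotypes
compatible with at least one individual — deterministic, so no seed enters
the estimator. Convergence: max absolute frequency change < 1e−8
(`tol`), capped at 10,000 iterations (`max_iter`), with the result flagged
non-converged past the cap. The log-likelihood is asserted non-decreasing
at every iteration (tolerance 1e−9 for float noise); frequencies below the
prune threshold 1e−12 are dropped and the rest renormalized. The EM
likelihood is multimodal in general; uniform initialization is the
conventional deterministic choice and recovers planted frequencies to
< 0.02 at N = 2000 in the acceptance run.

**Assignment.** Against a reference frequency table, each compatible pair
scores f(h₁)f(h₂)·(2 if heterozygous). Haplotypes absent from the table
receive pseudo-frequency ε = 1e−9 — far below any real table entry, so
listed pairs always dominate, yet every pair remains scoreable (reference
tables are finite and truncated, and unlisted haplotypes must still rank).
Exact score ties are flagged ambiguous and broken lexicographically for
determinism.

**Classification.** Known = exact two-field match at all loci. Variant =
exactly one divergent locus from the closest reference; divergence that is
only a G-group substitution still classifies as variant (flagged), since
typing methods cannot separate those alleles. Unknown = ≥ 2 divergent loci
from every reference. When several references sit at distance 1, the
highest-frequency one is chosen — a deterministic reading of "closest".
Variant suffix letters (b, c, d, …) are assigned per reference in
discovery order within an analysis run, via an explicit registry object;
whether such labels should be global across runs is a curation question
outside the package's scope.

**DRB3/4/5.** The secondary DRB loci travel in fixed linkage with DRB1
allele groups: DR1 (01, 10) and DR8 (08) carry DRB1 alone; DR51 (15, 16)
adds DRB5; DR52 (03, 11, 12, 13, 14) adds DRB3; DR53 (04, 07, 09) adds
DRB4. The table ships as an editable TSV; a DRB1 group without an entry
raises an explicit unresolved error rather than guessing.

## Cohort statistics

Allele frequencies are occurrence counts over 2N chromosomes; homozygotes
contribute 2. Individuals without a consensus genotype at a locus are
excluded from that locus (never imputed) and the exclusion count is
reported. Homozygosity is two-field, suffix-insensitive identity of the
consensus pair; multi-locus rates support both "all loci of a set"
(e.g. DQA1-DQB1 jointly) and "≥ k loci of a set" forms, with individuals
unresolved at any member locus excluded from that set's denominator.

The screening criteria are evaluated i → ii → iii with the first firing
criterion recorded (overlaps are possible; a single flag per allele is
reported). RA = patient/control frequency; RA is undefined when the
control frequency is 0 and such alleles are flagged patient-only without a
ratio. Control tables are inputs: published control sets should be
averaged upstream (an unweighted mean across sources is the default
reading; weighting by source N is a user decision), and the bundled
control fixture is synthetic, for tests and demos only.

Ancestry assignment is a threshold rule on externally computed
superpopulation fractions (EUR/AFR/AMR/EAS/SAS): the unique fraction
≥ 0.70 (inclusive) wins, otherwise admixed. The PCA machinery that
produces the fractions is out of scope.

## LOH from allele-specific copy number

Coordinates are 1-based inclusive internally (Sequenza convention); BED
input is converted on read and the conversion logged. Filters: segment
size ≥ 50 kb, sample tumor cellularity ≥ 0.2, overlap with ≥ 1 targeted
gene; every rejection is logged with its reason, and samples without a
cellularity/ploidy profile are rejected wholesale.

All LOH categories require complete minor-allele loss (B = 0); the
retained-allele copy number ("CNA") is the major allele A. CNt = 0 is
biallelic loss regardless of A/B availability. The amplification bound is
CNt ≥ 7 at ploidy 2 and CNt ≥ 1 + 2·ploidy at ploidy 3–9; fractional
ploidy is rounded half-up first because the rule is stated on integer
ploidies. Ploidy outside 2–9 leaves a B = 0, CNt ≥ 3 segment as LOH+gain
(logged) — the amplification rule is explicitly bounded. Segments without
A/B are unclassifiable (category none, flagged); A + B ≠ CNt is a
record-level error, not silently repaired.

Gene attribution is any-base overlap. When several segments cover one
gene the most severe category wins, with precedence biallelic-loss > LOH >
CN-LOH > LOH+amplification > LOH+gain > none (an ordering the rules
themselves leave open; chosen so that harder losses dominate, and logged
via the retained audit trail of all overlapping categories). Arm-level
calls require ≥ 90% coverage of the arm interval.

Prevalence policy: for HLA genes the numerator counts any of {LOH,
CN-LOH, LOH+gain, LOH+amplification} and the denominator excludes
patients germline-homozygous at that gene (one-allele genotypes cannot
exhibit allelic loss against a reference); for *B2M* and *CIITA* only
{LOH, biallelic loss} count, and no homozygosity concept applies. The
denominator is an explicit argument (the evaluable sample list), so
whether it is "all evaluable tumors" or "genotyped tumors per cohort" is
visible in every result row rather than implicit. Samples with unknown
germline genotype at an HLA gene are excluded from that gene's denominator
and logged. Identifying *which* allele is lost is out of scope — a known
limitation of reference-based copy-number analysis.

## Somatic filtering

"Fraction of mutated reads" is the variant allele fraction alt/(alt+ref);
zero-depth records have undefined VAF and fail with reason missing-data.
The four conditions (normal alt < 4, normal VAF < 0.06, tumor alt > 3,
tumor VAF ≥ 0.15) are conjunctive; note the asymmetric strictness — "less
than 4" and "more than 3" are strict, the tumor VAF bound is inclusive.
Consequence classes are consumed as annotation (annotation engines are out
of scope); splice-site variants count as non-silent by default. The
78-gene antigen processing and presentation set ships as an editable TSV
labeled with its KEGG hsa04612 provenance. The tumor-cellularity gate
(≥ 0.20) is applied at the sample level, reusing the copy-number sample
profiles.

## qPCR quantification

Quantity = 2^(mean reference Ct − target Ct). Normalizing on the Ct scale
with the arithmetic mean of reference Cts is mathematically identical to
the geometric mean of per-reference 2^ΔCt quantities (the identity is
asserted in tests to 1e−12) and avoids overflow for large ΔCt. Replicate
Cts are averaged arithmetically on the cycle scale. Undetermined Cts are
reported as missing, never as zero — negligible transcripts are absent
values, not measurements. Standard curves regress Ct on log₁₀ input
quantity over ≥ 3 dilution points; efficiency = 10^(−1/slope) − 1, so a
perfect doubling chemistry (slope −1/log₁₀2 ≈ −3.32) has efficiency 1.
Reference-gene stability selection is out of scope; the reference set is
configuration.

## Synthetic data generator

The generator emulates the statistical structure each stage assumes, not
the underlying reads. Genotypes: a pool of K haplotypes (default 8) over
3 loci with Dirichlet(1) frequencies, individuals formed by two
independent draws (random mating — which is exactly what makes the Σf²
homozygosity check valid). Alleles are shared across pool haplotypes
(5 alleles per locus by default) so phase is genuinely ambiguous and the
EM is actually exercised. Observed calls are corrupted per algorithm run:
miscalls replace an allele with a uniformly chosen different pool allele
(ε = 0.01 by default, consistent with the > 99% accuracy the integrated
callers report on the main loci), dropout reports a single allele
(δ = 0.01) — the two failure modes the consensus rule exists to absorb —
and RNA-material calls at a silenced (patient, locus) report one allele or
none, emulating transcript silencing (default probability 0.05 at HLA-B,
the locus expression data show most often silenced; the default cohort
size of 576 mirrors a realistic study). Segments, variants and Ct tables
are generated from explicit planted plans: copy numbers are emitted
consistent with each category's definition, variant alt counts are
binomial around planted VAFs (with borderline plants near the 0.15 bound),
and Ct values are baseline − log₂(quantity) + Gaussian noise with the
reference genes at baseline. A planted segment can span neighbours of its
named gene in the dense HLA region; the recorded truth covers every gene
the emitted interval touches, so end-to-end recovery checks are exact.

What the generator does **not** emulate: read-level artifacts (alignment
bias, coverage dips in polymorphic exons), realistic linkage
disequilibrium beyond the pool construction, subclonal copy-number
mixtures, sequencing-depth variation along segments, or inter-run qPCR
effects. Passing tests therefore demonstrate the correctness of the rules
and estimators on data satisfying their assumptions — not robustness to
upstream artifacts in real cohorts.

A single top-level seed derives independent per-stream sub-seeds
(cohort/segments/variants/expression), so each stage is reproducible in
isolation and identical (config, seed) gives identical outputs.

## Problem sizes

Default verification scales: EM recovery at N = 2000 individuals, K = 8
haplotypes (estimation error comfortably under 0.02 against sampling noise
of ≈ 0.008 SD); diplotype-assignment agreement on 1000 random genotypes;
consensus checks on 120-patient cohorts; the LOH truth table exhaustively
over CNt ≤ 12 and ploidy 2–9; the somatic oracle on 10,000 records; HWE
calibration at N = 1000. These sizes make every statistical check
well-powered while keeping the full suite and the acceptance script in the
seconds range.

## Known limitations

- Consensus treats sample identifiers as the unit of replication; technical
  replicates sharing an identifier cannot add support.
- The EM provides point estimates only; no confidence intervals or
  bootstrap.
- Variant suffix letters are stable only within a run (registry scope).
- The bundled G-group, control-frequency and reference-haplotype tables
  are small fixtures (the latter two explicitly synthetic); real analyses
  must supply curated tables.
- LOH classification trusts the segmenter's A/B/CNt and cellularity/ploidy;
  no re-estimation or uncertainty propagation is attempted.
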