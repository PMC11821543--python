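# Methods

This note records the models, conventions and numerical choices behind
`sdpanpop`, and what the synthetic cohort does and does not emulate.

## Coordinates, projection and the region catalog

All intervals are 0-based half-open (BED convention), in memory and on
disk, and chromosome names are taken verbatim from input.  Haplotype SD
calls arrive in assembly coordinates and are projected to the reference
through 1-to-1 alignment blocks.  Blocks are modeled gap-free: within a
block the mapping is a constant offset (forward strand) or a mirror
(reverse strand); indels live at block boundaries.  This is sufficient for
interval projection without CIGAR algebra, at the cost of representing
sub-block indels as boundary fragments.  Interval portions covered by no
block are returned as "unplaced" and excluded from the catalog (population
statistics are restricted to 1-to-1 syntenic sequence); their lengths are
tallied in a side table.

Projected intervals are flattened into their set-theoretic union
(touching intervals merge), giving nonoverlapping catalog regions.  A
haplotype is *present* in a region when its SD bases cover at least 50% of
the region's length (inclusive).  The 50% rule is a deliberate
reciprocal-overlap-style guard: strict-overlap presence would let a 1-bp
edge touch count as carrying the duplication, while a much higher cutoff
would be brittle to boundary jitter between independently assembled
genomes.  The same 50% rule decides whether a region is "in the
reference" relative to the reference SD annotation.

Frequency classes partition the catalog: **fixed** is evaluated at the
haplotype level (all H haplotypes), **private** at the sample level
(exactly one carrier sample, absent from the reference); a non-fixed
region in the reference is **polymorphic (known)** even with a single
carrier sample, because the reference itself is evidence of recurrence;
non-reference regions with ≥ 2 carrier samples are **polymorphic
(novel)**.  Regions generated by both intrachromosomal and
interchromosomal pairs are tagged `both` and counted once in union
totals.

Accumulation curves attribute each region's bp to its first carrier in a
haplotype ordering (default: non-African block, then African block).  The
per-genome increment is reported both as the mean of the post-first
increments and as the least-squares slope of the cumulative curve; the two
differ whenever the curve is non-linear, so both are labelled explicitly.

## Pair properties

The distance between same-chromosome mates is the inner gap (end of the
left mate to start of the right mate, 0 when touching or overlapping) —
the conservative reading of "apart".  Dispersion classes are mutually
exclusive: clustered (gap ≤ 1 Mb), interspersed (1 Mb < gap ≤ 50 Mb),
distant (gap > 50 Mb); different-chromosome pairs are interchromosomal and
carry no gap.  Rarity bands use carrier counts: rare ≤ 5 carriers
(< 3% haplotype frequency at H = 170), common 6–20; for cohorts of other
sizes the counts stay primary and the allele-frequency fraction is
reported alongside.

Permutation comparisons relabel pooled values.  The default P value is
one-sided *in the observed direction* and is reported with that direction;
because the direction is data-chosen, treating this P as a fixed-level
test doubles its nominal type-I error, so the pre-specified alternatives
(`greater`, `less`, `two_sided`) are provided and are what the calibration
tests assert.  Monte-Carlo P values use the add-one estimator
(1 + #extreme)/(1 + n_perm); when the pooled size is ≤ 10 the full
assignment set is enumerated and the P is exact.  Enrichment 2×2 tables
use the sample odds ratio ad/bc with a two-sided Fisher exact P
(minimum-likelihood convention); a zero cell gets a Haldane–Anscombe
0.5-correction for the point estimate only, flagged in the result.

The proximity test measures the median distance from each novel region to
its nearest known SD and compares it against uniform random re-placement
of each region on its own chromosome (length-preserving, avoiding excluded
intervals).  The alternative ("closer than random") is fixed in advance,
so the null P is uniform; with n_perm = 199 the attainable P values make
the 0.05 level exact.

Inversion enrichment is computed over *distinct pair loci*, never over
per-haplotype pair records: orientation is a property of the duplication
event shared by all carriers, and carrier-weighted counts would
pseudo-replicate each event by its frequency.

## Copy number

Assembly CN counts filtered paralog hits per haplotype (coverage > 0.60
and identity > 0.90, both strict as printed cutoffs; genes with CDS
< 200 bp excluded; hits fully contained in repeat annotation excluded;
optionally hits within 30 kb of an assembly break).  Diploid CN is the
sum over a sample's two haplotypes.  Genes whose extra copies (count > 1)
occur in exactly one haplotype cohort-wide are flagged as candidate
assembly artefacts; whether they are excluded is a per-analysis switch,
since haplotype-resolved reporting needs them retained.

Read-depth CN tiles the genome in non-overlapping 1-kb windows
(configurable).  Windows overlapping tandem-repeat/low-complexity
annotation by strictly more than 10% are excluded.  GC correction is
fitted on a noiseless *self sample* — the reference decomposed against
itself at uniform expected depth — in GC bins of width 0.01 pooled
left-to-right to ≥ 100 windows per bin; the per-bin factor is bin mean
over global mean, so the model is the identity on unbiased input and a
fixed point under re-application.  Corrected depth becomes CN via
CN = 2·depth/baseline, with the baseline taken as mean corrected depth
over caller-supplied known-CN=2 ("unique") regions.  Gene CN is the
median over windows fully contained in the gene span.  Per-gene
adjustment factors a_g = assembly CN / read-depth CN on the
reference-matched self sample absorb systematic underestimation from
paralog divergence; genes with |a_g − 1| > 0.5 are excluded and tallied.
Family variability uses the index of dispersion with the n−1 sample
variance (the cohort sizes involved, tens of samples, make the unbiased
estimator the natural choice); rankings require mean diploid CN > 3.

## Population differentiation

Families are eligible when dispersion ≥ 0.1 *and* mean CN > 2 within the
African or within the non-African samples (union of the two group-wise
checks).  Eligible families get a two-sided Mann–Whitney U across groups —
exact by enumeration (tie-aware, average ranks, two-sided by distance of U
from mn/2) when the pooled size is ≤ 12, otherwise the tie-corrected
normal approximation with continuity correction — followed by
Benjamini–Hochberg adjustment over the eligible set.  Significance is
adjusted P ≤ α by default, with a strict-inequality switch for very large
replication cohorts.  The direction balance among significant families is
summarised by a one-sided exact binomial P toward the observed direction,
Pr(X ≥ max(k, n−k)) at p = ½ — the one-sided form is the convention this
analysis uses for its printed worked examples (13/16 → 0.01;
164/263 → 0.00004).  Replication across two cohorts requires significance
with the same direction in the second cohort.

## Iso-Seq filter

Gap-compressed identity is matches/(matches + mismatches + gap openings):
each gap counts once regardless of length.  A read is
reference-divergent iff haplotype identity > 0.999 and reference
gap-compressed identity < 0.997, both strict; a missing reference hit
counts as identity 0.  The haplotype side uses plain identity and the
reference side gap-compressed identity by default, with thresholds
exposed.  Candidate regions can be pre-filtered to those carried by at
most 10 haplotypes.  Family totals take, per family, the haplotype with
the most novel paralog predictions, so shared paralogs are not counted
once per carrier.

## The synthetic cohort

The generator emulates the *statistical structure* of a 170-haplotype
pangenome SD survey — 38 African and 47 non-African samples — on a toy
genome of three chromosomes totalling 30 Mb, a size that keeps a full
pipeline run around five seconds while leaving room for 1–100 kb SDs.
Defaults: 240 SD pairs with a fixed/polymorphic/private spectrum of
0.25/0.55/0.20; polymorphic carrier counts drawn 40/35/25% from the rare
(2–5), common (6–20) and higher bands; rare pairs drawn longer (log-normal,
median ≈ 8 kb vs ≈ 4 kb) and more identical (divergence ≈ 1.2% vs 3.5%);
dispersion mix 55% clustered, 30% interspersed, 15% interchromosomal;
inversion probability 0.20 for clustered pairs and odds ratio 2.0 for
interspersed; an African intrachromosomal excess realised as 30 extra
10-kb AFR-only clustered pairs at carrier probability 0.5 (expected
excess 300 kb per African haplotype); 50 gene families (1–3 genes each,
per-haplotype copy counts truncated Poisson), 10 of them with African
rates shifted by ×1.6; depth at 30× mean coverage with a quadratic GC
response, near-Poisson negative-binomial noise (size 200 — a mild
overdispersion consistent with modern short-read libraries), a 5% repeat
fraction with inflated junk depth, and 30% of genes attenuated (×0.72–1.0,
plus ~5% strongly attenuated past the 50%-adjustment exclusion) to
exercise the adjustment machinery; a 20-sample balanced depth cohort;
and planted reference-divergent Iso-Seq reads in 5 families.

Assembly frames are real: call sets are emitted in haplotype coordinates
through per-haplotype alignment blocks with indel offsets and one
mirrored (reverse-strand) block per chromosome, so projection is
exercised on every run; boundary jitter of ±100 bp per interval end
emulates assembly boundary noise while staying inside the 50% presence
rule.  A `pair_survey` configuration (two 60-Mb chromosomes dense with
~4,500 short pairs, four haplotypes, no depth stage) provides the ≥ 2,000
distinct interspersed pair loci needed to estimate the inversion odds
ratio tightly.

What the generator does **not** emulate: sequence content (no reads or
FASTA; the 36-mer self-decomposition is realised as a uniform-depth self
sample, which reproduces the defining property of the GC recalibration
without read simulation), NAHR mechanism or mutation-rate realism,
"distant" (> 50 Mb) pairs on the 30-Mb default layout (the class is
unit-tested on synthetic coordinates; its fraction is configurable for
larger layouts), acrocentric-arm pathology, assembly collapse, or any
spatial clustering of novel SDs near known SDs (novel placement is
uniform, so the proximity test's null behaviour — not the positive
effect — is what the suite checks).  Passing tests therefore demonstrate
correctness of the statistical machinery and end-to-end truth recovery
under a realistic noise model, not performance on real assemblies.

## Numerical and testing notes

* Degenerate inputs raise typed errors: empty intervals, zero margins in
  2×2 tables, zero-mean dispersion, constant predictors in R², baselines
  of zero, regions that cannot be placed.
* Ties: Mann–Whitney uses average ranks and tie-corrected variance;
  permutation tie-handling counts equal statistics as extreme (with a
  1e-12 tolerance), the conservative choice.
* Benjamini–Hochberg is the standard step-up (statsmodels); note it is
  *not* idempotent as an operator on P vectors — re-adjusting adjusted
  values inflates them — so only monotonicity and the constant-vector
  fixed point are asserted as properties.
* The exact and normal-approximate Mann–Whitney paths agree closely for
  moderate P but diverge relatively (≈ 2–3×10⁻² absolute, tens of percent
  relative) in the far tail at the n = 12 crossover; the crossover is
  therefore placed where enumeration is still cheap rather than where the
  approximation is perfect.
* The read-depth replication cohort in the default run has 20 samples;
  at that size the replication test is underpowered after BH correction
  (the discovery cohort's 85 samples carry the power), which mirrors the
  general design where the replication cohort's size, not the method,
  determines replication yield.
* Problem sizes in the test suite (30 Mb layouts, 200-replicate
  calibrations, 100-seed odds-ratio surveys, ≤ 1 Mb oracle instances)
  were chosen so the whole suite and the acceptance script each complete
  in a few minutes on one CPU.
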