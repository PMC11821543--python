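# sdpanpop

Population-level analysis of human **segmental duplications (SDs)** —
blocks of homologous DNA longer than 1 kb with more than 90% sequence
identity — across cohorts of haplotype-resolved genome assemblies.

Modern pangenome projects assemble both haplotypes of many individuals,
which makes it possible to ask, for every duplicated region of the genome:
is this duplication fixed in the species, polymorphic, or private to one
person?  Does it sit near other duplications?  Is it inverted relative to
its mate copy?  How many copies of each duplicated gene family does each
person carry, and do copy numbers differ between populations?  `sdpanpop`
implements that analysis as a reusable, tested library and CLI for
researchers in structural variation and population genetics.

## What it computes

* **Region catalog** — per-haplotype SD calls (assembly coordinates) are
  projected to the reference frame through 1-to-1 alignment blocks,
  flattened into nonoverlapping regions and classified as *fixed* (present
  in all H haplotypes), *polymorphic known* (in the reference, not fixed),
  *polymorphic novel* (absent from the reference, in ≥ 2 samples) or
  *private* (one sample), with haplotype frequency f = k/H and
  accumulation curves over the cohort.
* **Pair properties** — orientation (direct/inverted) × dispersion
  (clustered ≤ 1 Mb, interspersed 1–50 Mb, distant > 50 Mb,
  interchromosomal) classification; rare (k ≤ 5) vs common (6 ≤ k ≤ 20)
  contrasts by label-permutation tests; Fisher-exact 2×2 enrichment
  (e.g. inversion among interspersed pairs); a permutation test for
  proximity of novel SDs to known SDs.
* **Gene copy number, two ways** — (1) assembly-based: filtered paralog
  alignment hits (> 60% coverage, > 90% identity, CDS ≥ 200 bp) counted
  per haplotype and summed to diploid copy number (CN); (2) read-depth:
  1-kb windowed depth with > 10% tandem-repeat windows excluded, GC
  correction recalibrated on a noiseless reference self-sample, per-gene
  median of contained windows, and per-gene adjustment factors anchored to
  assembly CN (genes needing > 50% adjustment dropped).  Family
  variability is ranked by the index of dispersion, D = s²/x̄.
* **Population differentiation** — per-family Mann–Whitney U between
  African and non-African samples over families with D ≥ 0.1 and mean
  CN > 2, Benjamini–Hochberg correction, a one-sided exact binomial test
  on the direction balance, and two-cohort replication logic.
* **Iso-Seq novel-gene filter** — a full-length cDNA read supports a
  reference-divergent paralog iff its haplotype identity exceeds 99.9%
  while its gap-compressed reference identity stays below 99.7%;
  family counts take the haplotype with the most novel paralogs.
* **Synthetic cohort generator** — emulates the statistical structure of a
  170-haplotype pangenome survey (76 African / 94 non-African haplotypes)
  on a 30 Mb toy genome, with ground truth for every stage: frequency
  spectrum, rare-vs-common length/identity shifts, an African
  intrachromosomal excess, a 2.0 inversion odds ratio among interspersed
  pairs, population-shifted gene families and GC-biased overdispersed
  depth.

## Worked example

```bash
sdpanpop run --config configs/smoke.yaml --seed 4 --out runs/smoke
```

runs the full pipeline (simulate → catalog → properties → genecn →
depthcn → popdiff → isofilter) on a 10-haplotype cohort and prints the
consolidated report, e.g.:

```
seed 4  config 1183647be9bf50e3
SD regions: 112 covering 814,197 bp
class counts: fixed=34, polymorphic_novel=32, private=24, polymorphic_known=22
mean per-genome increment: 59708.7 bp (regression slope 66378.9)
interspersed inversion OR: 2.26 (P=0.314)
novel-SD proximity P: 0.7541
assembly vs read-depth CN R^2: 0.988
differentiated families: 0 of 9 eligible; AFR higher in 0 (binomial P=None)
replicated in read-depth cohort: 0
novel genes (Iso-Seq): 12 from 2 families
```

Reading the report: 112 nonoverlapping SD regions cover 0.81 Mb of the toy
reference; each added genome contributes ~60 kb of new SD sequence; the
interspersed-inversion odds ratio lands near its configured value of 2 but
is not significant at this size (tens of pair loci, not thousands); the two
copy-number methods agree at R² = 0.99; and population differentiation
finds nothing because a 2-vs-3-sample contrast cannot reach significance —
the exact Mann–Whitney floor at those sizes is P = 0.2.  At the default
cohort size (85 samples) the planted shifted families are recovered; see
the acceptance script below.  Every number is recomputed from the stage
outputs written under `runs/smoke/`.

Each stage is also available separately (`sdpanpop simulate`, `catalog`,
`properties`, `genecn`, `depthcn`, `popdiff`, `isofilter`) over the
documented TSV/BED file contracts, and everything is importable as a
library (`import sdpanpop`).

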