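# Methods

## Coordinate and counting conventions

All internal coordinates are 0-based half-open; BED input is taken as
0-based, GFF3 converted from 1-based inclusive on read. A methylation call
is addressed by the reference position of the modified base itself, so a
minus-strand 6mA sits on a reference `T`. The gene start site (GSS) and
gene end site (GES) are strand-aware transcription boundaries; the gene
body is the unspliced GSS..GES span (exons plus introns), and the promoter
is the 2 kb immediately upstream of the GSS (configurable), clipped at
chromosome ends.

Two views of the annotation coexist deliberately. The site-distribution
table uses an exhaustive, exclusive partition with precedence
exon > intron > promoter > intergenic, chosen because gene bodies are the
primary unit of the analysis. Per-gene summaries are instead independent
per gene: a site inside gene A's body and gene B's promoter counts for
both roles. Promoter 6mA counts therefore do not exclude sites shared with
an upstream gene's body; the exclusive partition is available when a
disjoint accounting is needed.

## Occupancy profiles

Occupancy in a window is methylated bases over countable bases of the same
letter. Windows are non-overlapping ("tumbling") of the stated width — one
reported value per 50 or 100 bp step, which is what a per-step sliding
summary reduces to. By default the denominator counts adenines on both
strands (reference `A` plus reference `T`) and the numerator pools calls
from either strand, because the quantity of interest — 6mA sites out of
total adenine sites — is strand-agnostic; a reference-strand-only mode is
provided. Windows truncated by a chromosome end contribute only in-bounds
positions, and windows with zero countable bases report an explicit NaN,
never a silent zero.

The metagene profile maps each gene body linearly onto a fixed number of
bins (default 60) between fixed-bp flanks (5 kb in 100 bp windows). Genes
shorter than two windows are excluded from body mapping and counted. The
random control draws up to 10,000 genes without replacement with a
recorded seed. The high-expression class uses focal-tissue FPKM ≥ 1 (the
comparator is configurable to strict >).

## Statistics

* **tau** uses xᵢ = log₂(FPKM + 1). The pseudocount makes the transform
  defined at zero and keeps x̂ᵢ in [0, 1]; base and pseudocount are
  configurable. tau is undefined (NaN) for genes silent in every tissue.
  tau is invariant to tissue permutation but *not* to rescaling all FPKM
  by a constant — the log transform makes x̂ scale-dependent; the test
  suite asserts the actual behaviour of both.
* **Context fractions** are anchored at retained (coverage-filtered)
  methylated cytosines. For each 5mC the three-base context on its strand
  is inspected; the denominator per context (CGN / CHG / CHH) is
  occurrences containing at least one adenine and the numerator is
  occurrences with at least one 6mA-methylated adenine, so a CAᵐAᵐ CHH
  occurrence counts once. An alternative denominator over all genomic
  context occurrences is deliberately not the default.
* **Contingency tests** are Pearson chi-square without continuity
  correction; all-zero margins are dropped and a table collapsing below
  2×2 is flagged degenerate, never coerced. Pairwise quartile-bin
  comparisons use Bonferroni over the six pairs; the overall 2×4 test is
  reported alongside.
* **Two-sample tests**: Welch's t (unequal variances, two-sided) wherever
  an unpaired t-test is called for; Mann–Whitney U with midrank ties,
  exact null distribution when n·m ≤ 400 and the pooled sample is
  tie-free, tie-corrected normal approximation otherwise.
* **Quartile bins** use linear-interpolation percentiles at 25/50/75,
  intervals closed on the right, ties to the lower bin. Cut points are
  always derived from the data at hand and printed with the result —
  published cut-point values are empirical quartile edges of a particular
  dataset, not constants of the method.
* Where two expression thresholds appear in the literature (FPKM 1 for the
  high/low split, FPKM 5 as a "low expression" coarse cut) both are plain
  config values used where each analysis applies.

## Homolog conservation

A gene is "6mA-modified" for every conservation analysis exactly when its
body carries ≥ 1 site; promoter sites never confer the flag. When several
genomes of one species are analysed, a helper marks a gene methylated if it
is methylated in any of them. Pair classes (maintained / changed / neither)
partition all pairs and are symmetric in the two genes. Best-hit ortholog
pairs keep, per query, the top-bitscore hit passing identity > 0.9 and
e-value < 1e-6 (ties: higher identity, then lexicographic subject id,
tie-breaks counted) and retain the pair only when both genes share an
orthogroup; the strict mode discards a query whose best hit falls outside
its OG rather than falling back to the next hit, with an opt-in fallback
flag. Orthogroup-size grouping reports both quartile groups of total copy
number and the coarse "<2 copies vs more" split, because the small-family
contrast admits either reading; edges are always printed. Ka/Ks contrasts
exclude pairs with Ks = 0 (undefined ratio) and "neither" pairs.

## Synthetic data

The generator emulates the study's input structure at desk scale. Defaults:
2 chromosomes × 1 Mb, 400 non-overlapping genes (gamma lengths, mean 2 kb;
geometric-like exon counts, mean 4), GC 0.39, 4 tissues, background 6mA
rate 0.015 per adenine, 3× enrichment within ±2 kb of the GSS, a logistic
expression link (slope 0.5 on log₂(FPKM+1)) multiplying the body rate, 5mC
per context (CG 0.4, CHG 0.2, CHH 0.05) placed positionally independent of
6mA, coverage above the read filters except a 10 % low-coverage decoy
fraction, and homology tables with per-type pair maintenance probabilities
(WGD/segmental 0.6, dispersed 0.45, proximal 0.35, tandem 0.3), a
cross-species conditional maintenance of 0.7 (vs 0.4 gain) and a +0.05
Ka/Ks shift for changed pairs over a lognormal(ln 0.2, 0.4) baseline.
These scales keep every full run and the whole test suite in the
seconds-to-minutes range on one CPU while leaving all planted effects
many standard errors above noise.

Methylation is an independent per-base Bernoulli draw — the simplest model
consistent with everything the pipeline measures. What the generator does
**not** emulate: spatial clustering of marks beyond the planted positional
factors, TE-associated methylation, read-level error structure, and —
importantly — gene-level heterogeneity in background methylation. Under an
i.i.d. 1.5 % per-adenine rate every kilobase-scale gene body contains
sites, so whole-pipeline runs at defaults have essentially no unmethylated
genes. Passing recovery tests therefore demonstrate correctness of the
measurement code under known conditions, not that real genomes look like
this; analyses that need both methylated and unmethylated genes
(feature-quartile enrichment, duplicate-type fractions, pair conservation)
are validated on gene-level planted flags, which the generator also
produces (per-type statuses, expression truth classes, expected strict
best-hit lists) in its truth manifests.

Determinism: all draws flow from one seed through per-stage child
generators; identical configurations give byte-identical output files, and
the pipeline report is byte-identical across reruns.

## Numerical choices and degenerate inputs

Empty site sets yield zero counts with an explicit flag rather than NaN
fractions; degenerate quartiles (fewer than four distinct values or
repeated edges) are an error naming the cause; an empty gene set after
expression filtering is an error naming the set; chi-square on a collapsed
table raises a typed error that callers convert into a flagged,
explained result. The occupancy engine uses prefix sums per chromosome, so
results are independent of site-file ordering and chromosome naming, and
reverse-complementing the genome (with coordinates and strands reflected)
leaves every profile unchanged — both asserted in the test suite.

## Known limitations

6mA calls are treated as independent per-base events; dyad or
strand-correlated calling is not modelled (each called base is counted on
its own). No motif discovery is performed — flank extraction feeds external
tools. Orthogroup inference, synteny, and Ka/Ks estimation from sequence
are consumed as tables, never computed. P-values from the chi-square
approximation are unreliable for very sparse tables; the package reports
the table alongside every statistic so exact tests can be applied
externally when counts are small.
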