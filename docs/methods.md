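# Methods

## Scope and data model

`omiclone` operates on one tumor sample at a time (optionally a pair for
the serial comparison), represented as eight typed relations: somatic WES
variants `W`, methylation probes `M`, copy-number segments `C`, raw gene
counts `H`, RNA variants `RV`, transcript quantifications `R`, a gene
list `K` (key genes and tumor suppressors) and experiment metadata `P`.
Relations are pandas DataFrames with declared schemas; the integration is
written as explicit relational algebra (selection, projection-distinct,
equi-join, left-outer join, keyed intersection/difference) so each stage
is auditable and testable against a naive nested-loop oracle.

Null semantics are standard: a null key never satisfies an equality
predicate, and nulls propagate through projections. Intersection and
difference between samples key on `(chromosome, position)` only, not on
the alternate allele — two distinct substitutions at one position count
as one locus. This is a deliberate, known coarseness of the comparison;
multi-allelic VCF records are nevertheless split on ingest, one variant
row per alternate. Duplicate elimination compares projected tuples after
rounding reals to 10 significant digits, so floating-point noise cannot
defeat deduplication.

Chromosome labels are normalized to `1..22, X, Y` (any `chr` prefix
stripped) so mixed UCSC/Ensembl inputs integrate cleanly.

## Variant quantification and filtering

`VAF = 100 * TRV / (TRV + TRR)` from tier-1 counts (Strelka dialect:
`AU/CU/GU/TU`, indels `TIR/TAR`) or allelic depths (GATK dialect: `AD`),
with the dialect auto-detected from the VCF header. Records with zero
supporting reads are skipped with a warning; a missing SnpEff `ANN`
field is a hard parse error naming the record. Per variant-gene pair the
highest-impact annotation is kept.

Default filters (all bounds inclusive): `4 <= VAF <= 100` percent,
`20 <= DP <= 1000` reads. Filtering is applied before the key-gene
intersection. Only MODERATE/HIGH-impact variants enter the integrated
relation.

## Integration and the evidence glyph

The pipeline composes four joins: impact-restricted variants to probes on
gene id (left-outer), RNA variants to transcripts with `FPKM > 0` and to
genes with `count > 0` (equi-joins), both attached to the variants by
`(chromosome, position)` (left-outer), and finally copy number by
closed-interval containment `start <= position <= stop` (1-based
coordinates). Segments must not overlap within a chromosome; a variant
inside two segments raises an integrity error. A variant with no covering
segment carries a null copy number, interpreted downstream as diploid
(CN = 2) — the neutral assumption for abundance and density weighting.

A mutation's glyph is `WES_PLUS_RNA` iff its locus matched an RNA variant
*and* the gene has expression support (an expressed transcript or a
positive raw count); otherwise `WES_ONLY`. Requiring expression support
in addition to the RNA variant call keeps the glyph aligned with what the
transcript table can substantiate.

The tumor-suppressor silencing screen runs on `M ⋈ H ⋈ K(TSG)` directly
rather than through the integrated relation, because silencing is
interesting precisely for genes *without* a somatic mutation; the
mutation-restricted variant (`mutated_key_gene_methylation`) is also
provided. Criteria: `beta >= min_meth/100` (default 0.25), regulatory
feature equal to "Promoter Associated" and CpG relation equal to
"Island", both matched case-insensitively after trimming since vendor
exports vary in case. A gene absent from the count table is treated as
count 0, as an exon-quantified gene with no aligned reads prints either
way depending on the counter's gene model.

## Clonality statistics

**Abundance and diversity.** Each retained mutation is one molecular
species with abundance `VAF * DP * CN`. The Shannon index
`SDI = −Σ p ln p` uses natural logarithms (nats) over abundance shares;
zero-abundance entries contribute nothing, an all-zero vector is an
error. `SDI = 0` for a single mutation and `SDI <= ln N` always, with
equality at uniform abundances; it is invariant under uniform rescaling
of abundances (so the percent-vs-fraction VAF convention cannot change
it). Simpson and Berger–Parker indices are available as optional extras
but are not part of any default report.

**Bandwidth.** The KDE bandwidth is the two-stage direct plug-in
selector for the Gaussian kernel, computed exactly (unbinned double
sums): scale `σ = min(sd, IQR/1.349)`; normal-reference
`ψ₈ = 105/(32√π σ⁹)`; `g₁ = (−2K⁽⁶⁾(0)/(ψ₈ n))^{1/9}` and the kernel
estimate of `ψ₆`; `g₂ = (−2K⁽⁴⁾(0)/(ψ₆ n))^{1/7}` and the estimate of
`ψ₄`; finally `h = (2√π ψ₄ n)^{−1/5}`. The selector is location
invariant and scale equivariant, and agrees with an independent R
implementation (`KernSmooth::dpik`, minimum scale estimate, level 2,
fine binning) to three significant figures on frozen samples — the
residual difference is the reference's binned approximation. With fewer
than 5 distinct values or zero spread it falls back to Silverman's rule
on the (weighted) sample, floored at 0.5 VAF points, rather than
crashing on degenerate inputs.

**Weighted density.** `f̂(x) = Σ w_i K((x_i − x)/h) / (h Σ w_i)` with
copy-number weights; with equal weights this reduces exactly to the
classical `1/(nh) Σ K((x_i − x)/h)`. Weights enter the density but not
the bandwidth selector: the selector runs on the raw VAFs, pairing an
unweighted bandwidth with a weighted density. The default evaluation
grid is 512 equispaced points on [0, 100] VAF percent with no boundary
correction; the trapezoidal grid integral of a well-contained density is
within [0.98, 1.02] of 1. Because the estimate is a convex combination
of kernels, `max f̂ <= 1/(h√(2π))`. Modes are strict local maxima on the
grid.

## Synthetic data

The generator plants a known clonal structure: VAFs drawn from a mixture
of truncated normals (defaults: clones at VAF 45 and 20, weights
0.6/0.4, sd 4 — a dominant near-clonal population plus a subclone, the
typical shape of a moderately heterogeneous exome), ~100 variants,
depths uniform on 30–300× (matching ~100× average exome coverage),
about a third of mutations mirrored into the RNA layers, four silenced
tumor suppressors out of eight, and a three-segment copy-number
landscape (CN 2/3/1) with one chromosome left uncovered so null-CN
handling is exercised. Variant read counts are back-computed from the
drawn VAF so `VAF = 100·TRV/DP` holds exactly and file round-trips are
lossless. Everything derives from one `numpy` `default_rng(seed)`, so a
fixed seed reproduces byte-identical bundle files.

What the generator does **not** emulate: mutational signatures, strand
or position biases, allele-specific expression, realistic
methylation–expression coupling beyond the silenced-TSG construct,
indels, or read-level noise. Passing tests therefore demonstrate the
correctness of the integration and statistics, not robustness to every
artifact of real sequencing data.

The worked two-timepoint case encodes a published myeloma patient's
per-gene summaries (key-gene mutations, expressed transcripts, TSG
methylation) at presentation and relapse. The summaries print no genomic
coordinates, so the case uses synthetic GRCh37-plausible loci, with
copy-number segments constructed around them to reproduce the printed CN
values; counts, depths, frequencies, betas and transcript FPKMs are the
printed values. Relapse rows marked "same mutation" resolve to the
presentation values.

## Numerical and design choices

* VAF is percent (0–100) everywhere; methylation beta is a fraction
  (0–1), with the percent threshold applied as `min_meth/100`.
* CNV intervals are closed `[start, stop]`, 1-based.
* When a VCF provides tiered allele counts, tier 1 is used.
* The per-mutation transcript lookup (tooltip-style, one locus) and the
  global expressed-transcript table are distinct operations; both are
  distinct projections of the integrated relation.
* Whether two alternate alleles at one position are one or two
  "mutations" in the sample comparison is resolved as one (locus
  keying), documented above.
* Plots write a sidecar TSV export of the plotted coordinates, colors
  and glyphs; tests assert on exports, never on pixels, keeping the
  contract backend independent. The depth color scale is log-spaced
  between the observed depth extremes. Labels use simple offset
  annotation rather than collision-aware placement.

## Problem sizes

The test suite and the acceptance script run on worked-case bundles
(5–13 rows per relation), randomized bundles of 5–100 variants (200 of
them for oracle equivalence), and planted two-clone samples of 260–300
variants; the bandwidth reference checks use n = 200–300. These sizes
fully exercise every code path of the method, whose statistics are
per-sample and scale linearly to real exomes (tens of thousands of
variant rows).

## Known limitations

* No subclone-number inference, clustering, or phylogeny: the density
  modes and diversity index are descriptive, not a mixture model.
* No statistical test on SDI differences between samples.
* The key-gene count matches on gene symbols as printed in gene lists;
  symbol drift between annotation releases is the caller's problem.
* Readers target the common export dialects (Strelka/GATK VCF,
  htseq-count, Cufflinks tracking, ExomeCNV-style segments, GenomeStudio
  450K tables); exotic column layouts need renaming to the documented
  aliases.
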