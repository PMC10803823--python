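# Methods

## Scope and model

`bvitpath` analyses the *potential* of a gut microbial community to
synthesise the eight B-vitamins. It works entirely on derived tables —
species abundance profiles, gene count matrices, similarity hits, genome
bin (MAG) annotations — not on reads; read QC, assembly, binning, gene
prediction, profiling and bin quality estimation are upstream tools whose
outputs this package consumes.

Each vitamin's biosynthesis pathway is represented by a catalog: a
MetaCyc pathway identifier (THISYN-PWY, RIBOSYN2-PWY, PYRIDNUCSYN-PWY,
PANTO-PWY, PYRIDOXSYN-PWY, BIOTIN-BIOSYNTHESIS-PWY, FOLSYN-PWY, PWY-5507)
and an ordered, duplicate-free list of reference gene accessions. Gene
identity throughout is accession-string equality; no sequence comparison
happens inside the package. The bundled catalog
(`data/synthetic_pathway_catalog.tsv`) is a synthetic stand-in with
realistic gene complements and symbols; any analysis can substitute its
own catalog file, and all completeness arithmetic is relative to whatever
catalog is loaded.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| MRA cut-off | 0.001 (0.1 %) | minimum mean relative abundance for a "modest or higher" biosynthesizer; inclusive |
| prevalence cut-off | 0.5 | minimum fraction of samples with non-zero abundance; inclusive |
| completeness threshold | 1.0 (B1,B2,B3,B5), 0.85 (B6,B7,B9,B12) | fraction of catalog genes required for a pathway to count as complete; the relaxed value absorbs the one-to-two genes of those pathways that annotation routinely misses |
| MAG contamination bound | ≤ 5 % | quality gate, inclusive; either bound violated discards the bin |
| MAG completeness bound | ≥ 90 % | idem |
| FDR level | 0.05 | Benjamini–Hochberg adjusted p ≤ 0.05 called significant, inclusive |
| normalisation | `cpm` (or `length_cpm` when lengths known) | per-sample scaling to 1e6; `length_cpm` divides by gene length in kb first (TPM-style) |

MRA is averaged over **all** samples, zeros included, so prevalence and
MRA share a denominator. Both core-selection cut-offs are inclusive, as
is the significance level.

## Design choices where the procedure was open

- **Median pathway abundance.** The pathway statistic is the median over
  *all* catalog genes of the per-reference-gene abundance (predicted
  genes mapping to the same reference are summed, family semantics;
  undetected references contribute 0). Treating the full catalog as the
  denominator follows from "all genes of a pathway"; the alternative
  reading (median over detected genes only) is available via
  `detected_only=True` / `--detected-only` and is reported, never
  silently mixed.
- **RBH tie-breaking.** Best hits are chosen by bitscore, then percent
  identity, then lexicographically smallest subject id. The tie-break is
  arbitrary but fixed so that repeated runs are byte-identical. No
  e-value threshold is applied by default; `max_evalue` is available.
  When annotation labels and RBH disagree on a gene, the annotation wins
  and the conflict is logged.
- **MAG filter conjunction.** "Contamination > 5 % and completeness
  < 90 %" is applied as discard-if-either: the two are independent
  quality gates and the kept set is exactly {contamination ≤ 5 % ∧
  completeness ≥ 90 %}, boundaries kept.
- **Strict vs loose pairs.** All qualifying pairs are reported; the
  `strict` flag marks pairs where neither member reaches the threshold
  alone, and a `--strict-only` switch restricts output. This preserves
  both readings of "pairs forming a complete pathway".
- **ANOVA on prevalence.** Prevalence per group is a single number, so
  the 3+-group comparison runs one-way ANOVA on per-sample 0/1 presence
  indicators, which restores sample-level replication. This is an
  interpretation, stated here deliberately.
- **Proportion test.** The two-group test is Pearson's chi-square on the
  2×2 presence table with the Yates continuity correction on by default
  (the convention of the classical equal-proportions test). Degenerate
  tables (a zero margin) return statistic 0, p 1 with a warning rather
  than failing.
- **Skewness test.** Abundance/prevalence distributions are summarised by
  moment skewness g1 = m3/m2^{3/2}; the p-value is a two-sided bootstrap
  under a symmetry null obtained by resampling from the sample pooled
  with its reflection about the mean, with the +1 continuity adjustment.
  On extremely heavy-tailed samples the symmetrized null itself has high
  skewness variance, so power grows slowly with sample size; the test is
  a descriptive check, not an inferential centrepiece.
- **Transporter consistency.** Pathway status is `complete`
  (completeness ≥ threshold — so a 0.9-complete B12 pathway is complete
  under the relaxed threshold), `absent` (0) or `partial`. A
  precursor-uptake transporter is consistent with partial or complete
  status; a product transporter only with complete. Transporters absent
  from a genome yield no flag.

## What the simulators emulate

**Cohorts.** Background species draw a prevalence from a right-skewed
Beta(0.6, 2.4) and an abundance location from a log-normal
(μ = 3, σ = 2 by default), reproducing the regime where most gut species
sit below 25 % prevalence and 0.01 % MRA and the across-species
abundance distribution is strongly right-skewed. Planted core species
are calibrated against the expected background total so their expected
MRA and prevalence hit stated targets; per-sample counts are rounded
log-normals (within-species σ = 0.5) thinned by Bernoulli presence.
Group effects shift presence probability additively (clamped to [0, 1],
clamping logged) or abundance multiplicatively. The default scenario
mirrors a three-cohort design — two urban groups of 55 samples and one
pooled tribal group of 31 — with a planted panel spanning the selection
boundary.

**MAG communities.** Planted pairs split one pathway's catalog into two
disjoint subsets, one per genome, and carry nothing else. For
full-completeness pathways several pairs coexist via a sunflower design
(pair *i* holds {gene₀, geneᵢ} vs the rest), chosen so that every
cross-pair union misses at least one gene; relaxed-threshold pathways
tolerate missing genes, which defeats that argument, so they host one
pair each (scenario validation brute-force checks cross-pair safety and
warns when a custom scenario breaks it). Background genomes carry each
catalog gene independently with probability `background_retention`.
Qualities are drawn inside the passing region unless overridden;
coverage is positive everywhere unless masked; transporters, when
enabled, are assigned consistently with each genome's pantothenate
status.

**Gene counts.** Per catalog gene and sample, counts are Poisson with
mean = true pathway abundance × a gene factor (default 1), so the median
estimator's recovery error at abundance λ concentrates within ~3√λ.

**Randomness.** A single scenario seed feeds per-element substreams
(seed word plus a CRC32 hash of the element name), so adding a species
or MAG never perturbs another's draws, and identical scenarios give
byte-identical outputs.

What passing tests on these simulations do **not** show: profiler
compositional bias, strain heterogeneity, chimeric bins, annotation
error correlated across genes, or covariate structure (age, diet)
confounded with group labels. Differential-abundance modelling of counts
(negative-binomial shrinkage, covariate-adjusted linear models) is out
of scope; the package's tables are formatted so those external tools can
consume them.

## Problem sizes and numerical notes

The test suite and the acceptance script run the pipeline at desk scale:
cohorts of 200–400 samples with 200–800 species, MAG communities of
10–35 genomes, 100 random instances per oracle-equivalence check, 1000
replicates for null calibration and Benjamini–Hochberg verification.
Type-I calibration of the two-group test is measured with the
uncorrected statistic (the Yates correction is deliberately conservative
at n = 50 per group; both numbers are reported). Medians use the
midpoint convention for even counts; even-split validation, inclusive
boundaries and degenerate-input behaviour (constant samples, zero
margins, all-zero columns) are fixed as described above and covered by
tests.

## Known limitations

- Complementarity is pairwise only; triples or larger consortia are not
  searched.
- Pathway completeness is presence/absence of catalog genes; no gene
  expression, flux, or exchange-metabolite feasibility is modelled.
- The curated known-biosynthesizer list and the reference catalog ship
  as synthetic stand-ins; analyses of real cohorts must supply the real
  tables in the documented TSV dialects.
- Annotation-label matching is exact normalized-string equality; no
  fuzzy synonym resolution.
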