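# Methods

## Problem and scope

`ffpeqc` quantifies how variant calling on formalin-fixed paraffin-embedded
(FFPE) whole-exome data deviates from matched fresh-frozen (FF) data. It
takes the text artifacts a standard alignment-and-calling pipeline already
produces — VCFs, a target BED, per-base depth tracks, read placements,
duplicate flag counts — and computes concordance, artifact, somatic-overlap
and coverage indicators. Upstream steps (alignment, duplicate flagging,
recalibration, calling, read re-sampling) are out of scope and assumed
done; so is annotation-database retrieval, which is replaced by a generic
key join on user-supplied tables.

## Variant model and filtering

A call set holds one record per `(chrom, pos, ref)`; multi-allelic sites
stay single records with the full alt list, because the pair comparison
asks "did the two samples make the same call at this position", not "do
they share an allele". A record is an SNV iff the ref and every alt are
single bases. Quality filtering keeps records with DP ≥ `min_dp` (default
13) and MQ ≥ `min_mq` (default 43), both inclusive; DP comes from the
sample FORMAT field with INFO/DP as fallback, MQ from INFO/MQ. Records
missing either annotation fail the filter conservatively and are tallied
separately ("unfilterable"), since a call whose depth is unknown cannot be
shown to meet a depth threshold. Chromosome names are normalized to a
`chr` prefix on read. VCF positions are 1-based; BED inputs are 0-based
half-open, converted only at I/O boundaries.

## Pair concordance

For one matched pair and one variant class, common positions are the
shared `(chrom, pos, ref)` keys (a ref mismatch at the same coordinate is a
representation difference, not a shared call). With FF as the reference,
an FFPE call is concordant when its alt set matches — and, in the default
`genotype` mode, its unordered genotype too. The looser `allele` mode
(alt sets only) exists because "the same base call" is genuinely ambiguous
between the two readings; the stricter one is the default as the safer
interpretation. Reported quantities:

* concordance rate `P = 100 · Nco / NPos`, rounded half-up to 2 decimals
  (table convention; banker's rounding would print 99.98 for 99.985);
* commonality fraction `100 · NPos / (NFF + NFFPE − NPos)`. The union
  denominator is a deliberate choice: it is symmetric in the two samples
  and reproduces the published minima (86 % SNV, 67 % INDEL) from the
  bundled count tables, which a plain NFF denominator does not.
* per-kit summaries of `|NFF − NFFPE|` with even-length medians averaging
  the two middle values (this reproduces the published kit medians
  214 = (190+238)/2 and 667 = (589+745)/2 exactly).

## Substitution spectrum

Counts over the 12 ordered ref>alt SNV classes, as written on the VCF
reference strand; each alt allele of a multi-allelic SNV contributes one
count, and the denominator of the pooled C.G>T.A rate is all counted alt
alleles. C>T and G>A are summed, not strand-collapsed per record, because
the deamination artifact surfaces on both strands and only the pooled rate
is interpreted. The FFPE−FF difference of this rate estimates the artifact
excess. A 6-class pyrimidine-collapsed view is provided for consistency
checks only.

## Somatic subtraction and overlap

Tumor-specific variants are tumor records whose full allele key
`(chrom, pos, ref, alt)` is absent from the matched normal — a different
alt at the same site is still somatic. No VAF or depth threshold beyond
the global filter is applied; the protocol is deliberately minimal.
Subtraction runs per condition, and the FF/FFPE overlap of the two
tumor-specific sets is counted on allele keys, with percentages of either
set rounded to integers for reporting. Cross-sample aggregation records,
per allele key, the number of carrying samples and per-condition mean VAF
(percent) and depth; annotation is a left join against user tables keyed
positionally or by gene symbol, keeping unmatched variants.

## Coverage indicators

All denominators are the merged target space, with targeted bases absent
from the depth track counted as depth 0 — coverage dropout must lower the
indicators, not shrink their denominator. Median coverage uses the
mean-of-middle-two convention. A read is on-target with ≥ 1 base of
overlap with any target (the common capture-QC convention; nothing in the
comparison is sensitive to this choice at exome scale). QC gates default
to ≥ 80 % of positions at 30X, median ≥ 60X, duplicates ≤ 25 %, and are
configurable. Sample read counts below 80 M are a sheet-validation warning
only; re-sampling is upstream.

## Group statistics

Welch's unequal-variance t-test (two-sided, Welch–Satterthwaite df) and
one-way fixed-effects ANOVA (df = (k−1, N−k)), computed via scipy with the
df made explicit. Two-sided p-values throughout. Two identical constant
groups report t = 0, p = 1; all-identical ANOVA groups report F = 0 with a
warning rather than 0/0. These tests are validated against closed-form
hand computations and null simulations (type-I error ≈ α over 10⁴
replicates), not against published statistics, whose raw per-sample inputs
are not available.

## Synthetic-data generator

The generator emulates a deep FF/FFPE whole-exome comparison at the
variant-list level on a synthetic two-chromosome 10 Mb coordinate space —
large enough that ~4×10⁴ variants never collide, small enough for
desk-scale runs. Defaults are the study conditions and are set once:

| parameter | default | rationale |
|---|---|---|
| n_germline | 44 700 | ≈ 41k SNVs + 3.7k INDELs per FF sample |
| snv_fraction | 0.918 | observed SNV:INDEL ratio |
| ffpe_dropout | 0.029 | ~3 % of FF calls missing from FFPE |
| ff_private_rate | 0.002 | small FF-only remainder |
| artifact_rate | 0.0097 | FFPE-private calls ≈ 1 % of the call set |
| discordance_prob | 1.5×10⁻⁴ | Ndi ≈ 6 per 4×10⁴ shared positions |
| background_cgta | 0.362 | C.G>T.A share of true SNVs |
| depth_mean FF / FFPE | 87.6 / 74.3 | condition mean median coverages |
| dup FF / FFPE | 0.079 / 0.122 | duplicate-read fractions |
| off_target FF / FFPE | 0.213 / 0.196 | off-target read fractions |
| n_somatic, det_ff, det_ffpe | 1200, 0.36, 0.38 | expected overlap ≈ 164 |

Mechanics: germline positions are drawn without replacement; FFPE sets are
the core minus Bernoulli dropouts, plus Poisson(artifact_rate·n_germline)
C>T/G>A SNVs at fresh positions, with Bernoulli(ε) discordance at shared
positions (alt swap by default; genotype flip as an alternative mode
matching the genotype concordance mode). DP is Poisson around the
condition mean, MQ normal(60, 1.5), het AD binomial(DP, ½). Depth tracks
are per-base Poisson; read placement realizes a Binomial off-target count
exactly in inter-target gaps; duplicate counts are the rounded fraction of
total reads. Every injected quantity is recorded in a truth ledger at
injection time. Identical configs (including seed) produce byte-identical
fixture bundles.

What the generator does **not** model: read-level errors, fragment-length /
DNA-integrity effects, GC or capture bias, trinucleotide context of
deamination (so no 96-class signature analysis), sample elimination, or
joint tumor-normal likelihoods. Passing recovery tests therefore show the
*measurement* code is unbiased under the assumed structure, not that real
FFPE artifacts follow these distributions. One known tension: with a
positionless injection model, an FFPE-private call fraction of ~1 % implies
a C.G>T.A rate excess of ~0.6 %, slightly below the ~1 % a real comparison
reports; matching both simultaneously would require artifact calls at
already-called positions, which the position-keyed concordance model
deliberately excludes. The count-matching default was kept.

## Validation strategy and problem sizes

* Exact oracles: hand-parsed VCFs, hand-classified fixtures, brute-force
  nested-loop pair scoring on random sets (≤ 200 records), sort-based
  medians, sum-of-squares ANOVA.
* Ledger exactness: measured Ndi, artifact counts, somatic overlap,
  off-target and exceedance fractions equal the ledger when interactions
  are disabled, and sit within 3 SE of expectation otherwise.
* Recovery at study scale: 200 seeded full-size pair simulations check the
  observed discordance fraction against the 3-binomial-SE band (per-seed
  band coverage for a Poisson(6)-level count is ~99.6 %, so ≥ 99 % of
  seeds is the pass line), and the FFPE-private C.G>T.A rate against the
  injected artifact rate. Somatic overlap uses 200 seeds at a reduced
  germline size (500) since the statistic depends only on the somatic
  component. Conservation properties run on 100 seeds at n_germline = 1200.
  These sizes keep the full suite a few minutes on one CPU while leaving
  Monte-Carlo error well below the tested tolerances.
* Published-count arithmetic: the bundled 25-pair tables are inputs; P,
  commonality, kit medians and overlap percentages are recomputed and
  asserted at printed precision.

## Limitations

Exact-key matching only (no indel equivalence classes, no distance-tolerant
matching, no phasing); INDEL "positions" assume upstream left-normalization;
annotation joins are exact-key; no multiple-testing correction (none is
needed for the handful of planned comparisons the tool reports).
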