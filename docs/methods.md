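# Methods

## Problem setting

Species-level taxonomic classification of long-read (nanopore) shotgun
metagenomes suffers from high false-positive rates: read-mapping
classifiers report hundreds of reference templates per sample, most of
them spurious cross-mapping. The conventional remedy is a minimum
relative-abundance threshold, which also removes genuinely present
low-abundance species. This package implements an alternative
post-classification route built on the classifier's *template identity*
metric, together with the benchmarking machinery needed to choose
operating thresholds and characterize detection limits on mock
communities.

## Template identity

For one reference template, the classifier's template identity is

    template ID = 100 × identical bases(consensus, template) / template length

where the consensus is the majority vote of the aligned reads. The metric
conflates two signals: breadth of reference coverage and similarity of the
covered part. A 100-base template covered across 75 bases has a maximum
template ID of 75%; 5 mismatches within the covered span lower it to 70%.
Hit tables usually report the percentage, not the numerator; the numerator
is reconstructed as `round(pct/100 × length)`, which inverts the
definition exactly up to rounding (the reconstruction error is bounded by
half a base).

## The template-identity route

Three steps turn per-template hits into one candidate record per species:

1. **Non-target removal.** Hits on plasmid-flagged templates are dropped
   (plasmids circulate among host species and carry little discriminatory
   signal), as are hits on viral templates (phage hits are frequent and
   non-specific). Plasmid status is a metadata flag; a helper flags
   templates whose description contains "plasmid" when no curated flag is
   available.
2. **Genome-level regrouping.** Templates of the same genome are summed:
   genome template ID = Σ identical bases / Σ template lengths. This is a
   length-weighted recomputation from the definition, never an average of
   per-template percentages. By default only templates present in the hit
   table enter the denominator; a `genome_lengths` option supplies full
   per-genome lengths so unhit templates contribute length (and zero
   identical bases) when that information exists. Hit-only is the default
   because it is computable from the hit table alone; the choice matters
   only for genomes whose templates are partially absent from the output.
   Genome coverage is computed in parallel (Σ covered bases / Σ lengths),
   with covered bases floored at identical bases so coverage ≥ identity
   always holds after rounding.
3. **Best-genome selection.** Per species, the genome with the highest
   genome-level template ID becomes the species call. Ties break by higher
   mapped-read count, then lexicographically smallest accession — both
   arbitrary but deterministic.

The **standard route** used as a comparator removes only viral hits, then
reports relative sequence abundance: species reads / total retained reads
× 100 (plasmid reads retained, no grouping or selection).

## Filtering, scoring, aggregation

A species call is retained when its metric (template ID or abundance) is
**≥** the threshold; "below the threshold" means absent, so the boundary
itself is kept. Detected-versus-expected sets give TP/FP/FN and precision,
recall, F1 on the 0–100 scale; FDR = 100 − precision. Metrics with a zero
denominator are undefined and propagate as missing — never as 0 — and are
skipped when aggregating. Across samples the aggregate is the elementwise
median (even-length lists: mean of the central pair); means are also kept
because they break ties during optimization. Species names on both sides
pass through an optional two-column synonym table, a format-stable
stand-in for taxonomy-service harmonization.

## Threshold optimization

Per-sample precision/recall/F1 are step functions of the threshold that
change only at observed metric values, so scanning the finite grid
{0} ∪ {observed values} reproduces a continuous scan exactly and cheaply.
Two selection strategies operate on the scanned curve:

* **max-F1** — argmax of the median F1; ties broken by the highest mean
  F1, residual ties by the lowest threshold (retains more species at equal
  measured performance).
* **FDR targets (15/10/5/1%)** — the lowest threshold whose median
  precision ≥ 100 − target. "Meets" is inclusive (a median precision of
  exactly 95% satisfies FDR5). An unattainable target is reported as an
  explicit marker, never silently replaced.

Thresholds are optimized per yield label (e.g. "500M"); labels are matched
as plain strings against the threshold table, with no unit arithmetic at
lookup.

## Read preprocessing

Reads strictly longer than 1,000 bp with mean Phred ≥ 10 are kept. The
default mean is error-rate based, −10·log10(mean(10^(−Qi/10))), matching
common read-QC tools and always ≤ the arithmetic mean (a switch selects
the arithmetic convention). Downsampling to a ladder of base yields draws
one seeded permutation and takes, per target, the shortest prefix whose
cumulative bases reach the target — the nesting requirement (each
higher-yield subset contains the lower-yield ones) forces a shared
ordering, and the prefix rule is its simplest deterministic realization.
Yield accounting uses post-filter reads only, since filtering precedes
downsampling.

## Limit of detection

The LOD is the lowest ground-truth sequence abundance such that every
expected species at or above it was still detected, evaluated on outcomes
pooled across samples. Species absent from the reference database are
excluded first (their misses measure database completeness, not
sensitivity), as are samples without abundance information. Candidates are
the observed abundances themselves, making the definition exact; an
interval-binned detection-fraction table is provided for presentation
only. At a tied abundance, every outcome at that level must be detected
for the level to qualify.

## Synthetic data generator

The generator emulates a mock-community benchmark without any downloads:
a reference of (by default) 30 expected and 6 decoy species, 3 genomes per
species, 4 templates per genome on a 4 Mb genome, plus plasmid templates
on half the genomes and a few phage templates. Per sample:

* expected species draw a genome-level template ID from a truncated
  normal (location 99, scale 2 on [0, 100]) multiplied by a coverage cap
  min(1, allocated bases / genome length), where allocated bases = yield ×
  abundance. The default abundance profile is geometric over ~3.3 orders
  of magnitude (≈21% down to ≈0.05%), so the cap couples abundance and
  yield to template ID the way breadth of coverage does in real data —
  at a 200M-base yield the expected-species median sits near 50% and rises
  to the high nineties at 2000M, while decoy species draw from a low
  truncated normal (location 3, scale 2.5) whose median stays near 3%
  across yields, with a small outlier tail whose upper bound grows with
  yield;
* sibling genomes of an expected species get attenuated identities
  (40–85% of the dominant genome's), so best-genome selection is
  non-trivial;
* each genome-level identity is decomposed into per-template identical
  bases proportionally to template length, with the remainder distributed
  under per-template capacity, so regrouping reconstructs the intended
  genome value exactly (up to rounding of the total);
* every template receives at least one mapped read, so at threshold 0 the
  detected set equals the configured species sets exactly.

All randomness flows from a single `numpy` generator seeded by the config;
no global state. The read simulator draws lognormal lengths and constant
per-read qualities, with knobs that force known fractions of reads to fail
the length or quality rule, so filter pass rates are predictable in
expectation.

What the generator does **not** model: real nanopore error profiles,
classifier multi-mapping resolution, shared templates between species,
database incompleteness (unless injected via `in_database`), and
contaminant ("kitome") structure. Passing tests therefore demonstrate the
correctness of the post-processing, optimization and LOD machinery under
the assumed TP/FP separation structure — not classifier accuracy on real
samples.

## Problem sizes and numerical choices

Tests and the acceptance checks run at desk scale: ten communities of ≤50
species, ~400 hits per sample, thresholds scanned over a few hundred
candidates; the full suite takes well under a minute. Parameter-recovery
checks train threshold selection on ten simulated communities and evaluate
on ten freshly generated held-out communities at 200M and 500M-base
yields, where threshold choice genuinely trades precision against recall;
the precision assertion allows the binomial sampling error of a 95%
proportion at the observed per-sample detection count. Percentages are
carried on the 0–100 scale end to end; comparisons against thresholds are
plain floating-point `>=` with no epsilon, since candidate thresholds are
drawn from the same values being compared.

## Known limitations

* The external classifier hook shells out with a fixed, documented flag
  set and parses the result table; it is optional and untested against a
  real classifier binary in CI-like runs (a mock executable covers the
  contract).
* Genome coverage at the template level is reconstructed from the rounded
  coverage percentage, so genome-level coverage is exact only to rounding.
* The pooled LOD is a point estimate by definition; no detection-curve
  modelling or per-sample LOD is attempted.
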