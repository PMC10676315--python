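# Methods

## Scope and model

The package compares length-based Y-STR genotypes called independently on
two platforms — capillary electrophoresis (peak heights, RFU) and
massively parallel sequencing (per-sequence read counts) — over a shared
panel of 19 loci, two of which (DYS385 a/b, DYF387S1) are multicopy and
yield up to two alleles per male. One locus (DYS392) ships in the registry
but is excluded from the MPS comparison (`mps_analyzed: false`) because
that marker consistently under-covers on the sequencing panel; the
comparative analysis therefore spans 18 loci.

A locus is described by an ordered list of motif blocks
`(motif, expandable, reference_count)`. The length-based allele number is
the total of counted-block repeats; microvariants carry the residual
nucleotides (`13.2` = 13 repeats + 2 nt). The reference sequence of an
allele is the block expansion with repeat-count variation carried by the
primary expandable block (the last expandable counted block).

## CE calling

Order of operations: (1) peaks below the peak amplitude threshold
(PAT, default 175 RFU) are noise and removed; (2) tallest-first, a peak at
a stutter position of an already-accepted peak (n−1, n+1, or n−2nt, i.e.
two nucleotides shorter) whose height ratio is within the per-locus filter
is labelled a stutter; (3) the remaining candidates face the calling
minima — a lone candidate needs ≥ 200 RFU (homozygous minimum), two or
more need ≥ 100 RFU each (heterozygous minimum). A lone survivor whose
partner dropped below the het minimum is held to the homozygous minimum,
since the genotype then looks homozygous. Whether the vendor applies the
100/200 RFU minima before or after stutter filtering is not documented;
the order above (thresholds last) is this package's documented choice.
Note that under the default configuration the 100-RFU het minimum is
vacuous — the PAT (175) sits above it — but the rule is implemented and
tested because both thresholds are user-configurable.

A peak that is simultaneously one repeat below one called allele and one
repeat above another is assigned to the minus-stutter interpretation
(minus stutter dominates empirically) and flagged `ambiguous_plus_minus`.

## MPS calling

Samples below 85,000 total run reads are excluded. The per-locus
analytical and interpretation thresholds are recalculated from locus
coverage as `⌈pct/100 · max(locus_reads, 650)⌉` — ceiling rounding is the
only rule reproducing both printed floors (1.5% → 10 reads,
4.5% → 30 reads at the 650-read basis). The vendor's exact recalculation
formula is proprietary; an alternative admissible reading (percentages of
raw locus reads with hard 10/30 floors) is available via
`recalc_basis: hardfloor`. Percentages are taken of total locus reads,
not of the maximum-allele reads — also a documented choice where the
vendor behaviour is unstated.

Sequences at or above IT are called unless attributable as stutter;
sequences strictly between AT and IT are grey-zone candidates, surfaced
but never auto-called — adjudication belongs to the comparison layer (in
the lab, to the operator). A locus with reads present but none reaching
IT is inconclusive (`low_coverage_inc`); a locus with no reads at all is
a clean dropout (deletion pattern), deliberately distinct so that a
deletion confirmed by both platforms can classify as concordant rather
than inconclusive.

Stutter identification is **sequence-exact**: a record is a stutter of
parent P only if its string equals P's sequence with exactly one repeat
of an expandable motif removed (n−1) or added (n+1). A one-repeat-shorter
sequence of a different variant string is *not* the parent's stutter. The
single per-locus filter value serves both stutter directions, as the
sequencing vendor's filters do; the calling filter never limits stutter
*observation* — observations are collected on every record above AT so
that stutters above the filter remain measurable.

### Bracket nomenclature

`bracket_sequence` first attempts a structured greedy parse (fixed blocks
match exactly, expandable blocks absorb maximal runs). Isometric variants
with substituted internal units fail that parse and fall back to
arithmetic typing (counted repeats = total unit chunks minus uncounted
fixed counts), which is only well-defined when every block is counted;
with uncounted blocks the sequence is a parse error, never a silent call.
The emitted notation is the run-length encoding of the repeat region, so
`expand(bracket(s)) == s` holds byte-for-byte for any accepted sequence
— a property tested over the full registry reference range and randomized
toy sequences.

## Comparison rules

Per sample × locus, in order of precedence:

1. MPS `low_coverage_inc` → `excluded_inconclusive`.
2. Equal sorted length-based allele sets → `concordant`, with notes for
   duplication (2 alleles at a single-copy locus), deletion (0 alleles on
   both platforms) and tri-allelic patterns.
3. Unequal sets where every CE-only allele matches an MPS grey-zone
   candidate length and MPS has no extra alleles →
   `apparent_discordant_grey_zone`. Near-misses stay `discordant`.

Grey-zone QC flags on an otherwise-equal call do not break concordance:
grey candidates adjudicate disagreements, they do not create them.

The multicopy overlap exclusion: when two called alleles sit exactly one
repeat apart, the larger allele's minus stutter co-migrates with the
smaller allele's signal (and vice versa for the smaller allele's plus
stutter), so both observations are emitted but marked excluded and
omitted from all stutter statistics. The rule is applied whenever two
called alleles are one repeat apart — multicopy heterozygotes in
practice, but the same physics covers a duplicated single-copy locus.

The allele census counts unique length-based alleles per locus (union of
platforms) plus unique MPS sequences deviating from the reference
expansion of their length allele (iso-alleles, variant homozygotes and
variant heterozygote sequences), deduplicated per locus.

Intra-locus balance is minor/major signal × 100 at multicopy
heterozygotes (heights for CE, reads for MPS; thresholds 65%/60%);
tri-allelic genotypes are excluded with a logged reason. "Student's
t-test" is implemented as the classic pooled-variance test with
`df = nx + ny − 2` (matching the method's naming); Welch's form is a flag,
since the equal-variance assumption is unverifiable from published
summaries. Zero-variance degenerate groups are defined: identical
constant groups give t = 0, p = 1.

The stutter detection frequency denominator counts samples passing the
read gate with a called parent allele at the locus (per allele copy at
multicopy loci) — the published summaries do not state their denominator,
so this one is documented rather than inferred.

## Synthetic cohort

Defaults are the stated world of the emulated study: 125 single-source
male profiles.

| parameter | default | rationale |
|---|---|---|
| reads per allele | negative binomial, locus means 213–3,091, panel mean ≈ 800, dispersion k = 8 | heavy-tailed amplicon coverage with the reported locus extremes (Y-GATA-H4 low, DYS438 high) |
| run total | Y-STR reads + N(78,000, 3,000) off-panel reads | the read gate operates on a full 153-marker run averaging ≈ 93,000 reads; the Y-STR subset alone carries ~15k |
| CE parent height | lognormal, mean 6,000 RFU, CV 0.30 | strictly positive, right-skewed; 1 ng template on a modern CE platform gives multi-thousand-RFU peaks, keeping a 5% stutter above the 175-RFU PAT |
| stutter ratio | normal truncated at 0; per-locus means ~3% (penta/hexa) to 30% (trinucleotide DYS481), sd 0.8–3 | reproduces the strong repeat-unit-length effect; means sit ≥ 5 sd below the calling filters so a clean cohort stays clean |
| plus stutter | mean 2.5% where emitted | mostly censored by the CE PAT but visible to MPS above its coverage-scaled AT — reproducing the observed many-fold CE/MPS asymmetry in plus-stutter counts |
| balance | minor = major × Beta(12, 2) | mean ≈ 0.86, occasional imbalance; the observed ILB equals the Beta draw, so threshold exceedance rates are analytically checkable |
| sequence variants | per-locus rates 0.08–0.15 at the eight designated loci; one internal unit of the primary run substituted at a fixed per-allele position | isometric by construction; recurring across carriers like real repeat-region haplotypes |

One per-locus stutter distribution drives both platforms (the
configuration surface defines a single distribution per locus), so
CE-vs-MPS stutter t-tests on default synthetic data are null by
construction — a green t-test machinery check, not a replication of
platform differences. Likewise the generator does not emulate: flanking
region variation, dye pull-up or other CE artifacts, n−2nt stutter (the
calling logic supports it; the default world does not emit it), PCR
inhibition, or mixtures. A green end-to-end test therefore establishes
that the threshold/stutter/comparison logic is correct under the stated
signal model, not that the pipeline is robust to every real-world
artifact.

Scenario injections occupy fixed sample slots (S001 grey-zone dropout at
DYS385 a/b with the dropout allele forced to 19 reads; S002 tri-allelic
37,38,39 at DYF387S1; S003 duplication at DYS448; S004 deletion at
DYS570; S005 low-coverage at Y-GATA-H4) so reports and tests can name
them.

## Numerical choices

- AT/IT recalculation uses ceiling rounding (see above); a degenerate
  `at ≥ it` after rounding is resolved as `it = at + 1`.
- A record with reads exactly equal to AT has not *exceeded* the
  analytical threshold and is discarded; the grey zone is the open
  interval (AT, IT); calling requires reads ≥ IT.
- Maximum-intensity ties in MPS calling break longer-allele-first, then
  lexicographic sequence — deterministic and documented.
- Multicopy copy labels (a/b) are assigned by ascending allele number.
- All tabular I/O is tab-delimited UTF-8 with a single header row; the
  registry is YAML with per-locus sections over a global `defaults:`
  section.

## Known limitations

- The shipped motif structures are simplified reference architectures
  (single primary expandable block, two-block compounds at DYS389II and
  DYS390, a fixed-block structure at DYS437); they are editable config,
  and no test depends on their fidelity to the authoritative ISFG tables.
- Arithmetic fallback typing cannot place variants in loci with uncounted
  blocks; such sequences error out for manual review.
- The census treats each distinct deviating sequence as one addition; it
  does not model flanking-region variants (out of scope of the configured
  repeat region).
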