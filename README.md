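# ystr-concord

Concordance analysis of forensic **Y-STR** genotypes between **capillary
electrophoresis** (CE, length-based typing from peak heights in RFU) and
**massively parallel sequencing** (MPS, sequence-based typing from read
counts). Written for forensic genetics labs validating an MPS workflow
against their established CE workflow on a shared panel of Y-chromosome
short tandem repeats, and for anyone who needs the underlying machinery:
platform-specific allele calling under stated thresholds, stutter-ratio
measurement, ISFG-style bracketed sequence nomenclature, and heterozygote
balance at multicopy loci.

## The analysis

For each sample × locus, both platforms are genotyped independently and
compared:

- **CE calling** applies a peak amplitude threshold (PAT, 175 RFU), filters
  stutter peaks (PCR slippage products at n−1, n+1 and n−2nt positions) at
  ratios within the per-locus filter, and calls alleles against 100/200 RFU
  heterozygous/homozygous minima.
- **MPS calling** gates samples at ≥ 85,000 total reads, recalculates the
  per-locus analytical and interpretation thresholds as
  `AT = ⌈at% · max(reads, 650)⌉` and `IT = ⌈it% · max(reads, 650)⌉`
  (defaults 1.5%/4.5%, giving the 10/30-read floors), types each repeat
  region into bracketed notation (e.g. `[TCTA]5 [TCTG]1 [TCTA]5`), and
  attributes sequence-exact stutters. Signal between AT and IT is a **grey
  zone**: surfaced for operator review, never auto-called.
- **Comparison** classifies each sample × locus as concordant, discordant,
  *apparent* discordant (every CE-only allele matches an MPS grey-zone
  candidate — the allele-dropout pattern caused by a primer-binding-site
  mutation), or excluded/inconclusive (MPS coverage never reaches IT).
  It also counts unique length- and sequence-based alleles (iso-alleles and
  isometric variants are MPS-only information), summarizes stutter ratios
  per locus, and compares intra-locus balance (minor/major signal of
  multicopy heterozygotes, thresholds 65% CE / 60% MPS) with a
  pooled-variance Student's t-test.

Because no real genotypes ship with the package, a synthetic-data module
generates paired CE/MPS tables with the cohort structure the analysis
assumes (125 males, 19 shared loci, negative-binomial coverage, lognormal
peak heights, per-locus stutter distributions, Beta-distributed balance),
plus injectable scenarios: grey-zone dropout, tri-allelic pattern,
duplication, deletion, low-coverage locus.

## Worked example

```sh
python analysis/01_simulate.py --seed 0     # writes results/sim/
python analysis/02_genotype.py              # writes results/calls/
python analysis/03_concordance.py           # writes results/concordance/
```

The final step prints (seed 0):

```
samples gated: 125 (excluded below read gate: 0)
sample x locus comparisons: 2250
  concordant: 2248
  discordant: 0
  apparent_discordant_grey_zone: 1
  excluded_inconclusive: 1
unique length-based alleles: 132
additional unique sequence-based alleles: 58

non-concordant sample x locus records:
  S001 DYS385 a/b: apparent_discordant_grey_zone (CE 14,19 vs MPS 14) ...
  S005 Y-GATA-H4: excluded_inconclusive (CE 13 vs MPS -) ...
```

Reading: 125 simulated samples × 18 MPS-analyzed loci = 2,250 comparisons.
The injected DYS385 a/b dropout is recognised as *apparent* discordance
(the CE-only allele 19 sits between the MPS thresholds at 19 reads), the
injected low-coverage locus is excluded as inconclusive, and everything
else — including the tri-allelic, duplication and deletion patterns — is
concordant. The census counts each distinct length-based allele once per
locus, plus the repeat-region sequences that deviate from the ISFG-style
reference expansion and are therefore visible only to MPS.

The same pipeline is available as a CLI:

```sh
ystr-concord simulate --seed 0 --n-samples 125 --out results/sim
ystr-concord concord --ce results/sim/ce_table.tsv --mps results/sim/mps_table.tsv \
    --sample-totals results/sim/sample_totals.tsv --out results/concordance
```

## Acceptance script

`scripts/acceptance.py` recomputes the analytically fixed quantities from
scratch by running the package: it loads the shipped locus registry, calls
the AT/IT recalculation at the minimum 650-read basis, runs a small
simulate-and-compare cycle as a smoke check, and writes the results as
JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/ystr_concord/` — the library: `locus_model` (registry, domain
  types), `synthetic_data`, `ce_typing`, `mps_typing`, `concordance`,
  `pipeline`, `cli_report`.
- `analysis/` — numbered narrative drivers over the library.
- `docs/methods.md` — model, parameter and design documentation.
- `tests/` — pytest suite including property-based checks.
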