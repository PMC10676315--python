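# Default locus registry: the 19 Y-STR loci shared between the two panels.
# DYS392 is retained for completeness but excluded from the MPS comparative
# analysis (mps_analyzed: false) because of its consistently low coverage.
#
# Motif structures are simplified reference architectures (canonical repeat
# unit, primary expandable block); the tests exercise the parsing machinery
# with toy motifs so nothing downstream depends on these transcriptions.
# MPS stutter filters sit in the vendor's 15-50% band; the two multicopy
# loci use the < 20% filter applied to both stutter directions.
defaults:
  pat_rfu: 175
  ce_het_rfu: 100
  ce_hom_rfu: 200
  mps_sample_read_gate: 85000
  mps_recalc_basis_reads: 650
  ilb_threshold_ce: 65
  ilb_threshold_mps: 60
  recalc_basis: floor650
  at_pct: 1.5
  it_pct: 4.5

loci:
  DYS19:
    copy_number: single
    repeat_unit_length: 4
    motif_structure:
      - [TAGA, true, 15]
    ce_minus_stutter_filter: 25
    ce_plus_stutter_filter: 8
    mps_stutter_filter: 25
    allele_range: [12, 18]
    dye: G
  DYS385 a/b:
    copy_number: multi
    repeat_unit_length: 4
    motif_structure:
      - [GAAA, true, 14]
    ce_minus_stutter_filter: 20
    ce_plus_stutter_filter: 8
    mps_stutter_filter: 19
    allele_range: [10, 20]
    dye: B
  DYS389I:
    copy_number: single
    repeat_unit_length: 4
    motif_structure:
      - [TCTA, true, 12]
    ce_minus_stutter_filter: 25
    ce_plus_stutter_filter: 8
    mps_stutter_filter: 25
    allele_range: [10, 15]
    dye: B
  DYS389II:
    copy_number: single
    repeat_unit_length: 4
    motif_structure:
      - [TCTG, true, 5]
      - [TCTA, true, 24]
    ce_minus_stutter_filter: 25
    ce_plus_stutter_filter: 8
    mps_stutter_filter: 25
    at_pct: 5.0
    it_pct: 15
    allele_range: [26, 33]
    dye: B
  DYS390:
    copy_number: single
    repeat_unit_length: 4
    motif_structure:
      - [TCTG, true, 8]
      - [TCTA, true, 16]
    ce_minus_stutter_filter: 25
    ce_plus_stutter_filter: 8
    mps_stutter_filter: 25
    allele_range: [21, 27]
    dye: Y
  DYS391:
    copy_number: single
    repeat_unit_length: 4
    motif_structure:
      - [TCTA, true, 11]
    ce_minus_stutter_filter: 25
    ce_plus_stutter_filter: 8
    mps_stutter_filter: 25
    allele_range: [8, 13]
    dye: Y
  DYS392:
    copy_number: single
    repeat_unit_length: 3
    motif_structure:
      - [TAT, true, 13]
    ce_minus_stutter_filter: 30
    ce_plus_stutter_filter: 8
    mps_stutter_filter: 30
    allele_range: [10, 16]
    dye: R
    mps_analyzed: false
  DYS437:
    copy_number: single
    repeat_unit_length: 4
    motif_structure:
      - [TCTA, true, 9]
      - [TCTG, false, 2]
      - [TCTA, false, 4]
    ce_minus_stutter_filter: 25
    ce_plus_stutter_filter: 8
    mps_stutter_filter: 25
    allele_range: [13, 17]
    dye: G
  DYS438:
    copy_number: single
    repeat_unit_length: 5
    motif_structure:
      - [TTTTC, true, 10]
    ce_minus_stutter_filter: 15
    ce_plus_stutter_filter: 8
    mps_stutter_filter: 15
    allele_range: [8, 13]
    dye: R
  DYS439:
    copy_number: single
    repeat_unit_length: 4
    motif_structure:
      - [AGAT, true, 12]
    ce_minus_stutter_filter: 25
    ce_plus_stutter_filter: 8
    mps_stutter_filter: 25
    allele_range: [9, 14]
    dye: G
  DYS448:
    copy_number: single
    repeat_unit_length: 6
    motif_structure:
      - [AGAGAT, true, 19]
    ce_minus_stutter_filter: 15
    ce_plus_stutter_filter: 8
    mps_stutter_filter: 15
    at_pct: 3.3
    it_pct: 10
    allele_range: [17, 24]
    dye: Y
  DYS460:
    copy_number: single
    repeat_unit_length: 4
    motif_structure:
      - [ATAG, true, 10]
    ce_minus_stutter_filter: 25
    ce_plus_stutter_filter: 8
    mps_stutter_filter: 25
    allele_range: [8, 12]
    dye: R
  DYS481:
    copy_number: single
    repeat_unit_length: 3
    motif_structure:
      - [CTT, true, 22]
    ce_minus_stutter_filter: 50
    ce_plus_stutter_filter: 8
    mps_stutter_filter: 50
    allele_range: [18, 30]
    dye: B
  DYS533:
    copy_number: single
    repeat_unit_length: 4
    motif_structure:
      - [ATCT, true, 12]
    ce_minus_stutter_filter: 25
    ce_plus_stutter_filter: 8
    mps_stutter_filter: 25
    allele_range: [9, 14]
    dye: R
  DYS570:
    copy_number: single
    repeat_unit_length: 4
    motif_structure:
      - [TTTC, true, 17]
    ce_minus_stutter_filter: 25
    ce_plus_stutter_filter: 8
    mps_stutter_filter: 25
    allele_range: [14, 21]
    dye: G
  DYS576:
    copy_number: single
    repeat_unit_length: 4
    motif_structure:
      - [AAAG, true, 18]
    ce_minus_stutter_filter: 25
    ce_plus_stutter_filter: 8
    mps_stutter_filter: 25
    allele_range: [14, 21]
    dye: B
  DYS635:
    copy_number: single
    repeat_unit_length: 4
    motif_structure:
      - [TCTA, true, 23]
    ce_minus_stutter_filter: 25
    ce_plus_stutter_filter: 8
    mps_stutter_filter: 25
    at_pct: 3.3
    it_pct: 10
    allele_range: [19, 26]
    dye: G
  DYF387S1:
    copy_number: multi
    repeat_unit_length: 4
    motif_structure:
      - [AAAG, true, 37]
    ce_minus_stutter_filter: 20
    ce_plus_stutter_filter: 8
    mps_stutter_filter: 19
    allele_range: [33, 42]
    dye: Y
  Y-GATA-H4:
    copy_number: single
    repeat_unit_length: 4
    motif_structure:
      - [TAGA, true, 12]
    ce_minus_stutter_filter: 25
    ce_plus_stutter_filter: 8
    mps_stutter_filter: 25
    allele_range: [10, 13]
    dye: R
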