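# Default region annotations for the bundled receptor/cytokine screen.
# Coordinates are 1-based inclusive positions in the full-length sequences.
# The cytokine entries are clustered candidate regions, not claimed
# secondary-structure boundaries.
proteins:
  TREM2:
    uniprot: Q9NZC2
    ig_domain: {start: 18, end: 130}
    regions:
      - {name: CDR1, start: 39, end: 46, kind: cdr}
      - {name: CDR2, start: 69, end: 75, kind: cdr}
      - {name: CDR3, start: 88, end: 91, kind: cdr}
      - {name: basic_strand_1, start: 47, end: 50, kind: basic_strand}
      - {name: basic_strand_2, start: 62, end: 68, kind: basic_strand}
      - {name: basic_strand_3, start: 76, end: 78, kind: basic_strand}
      - {name: basic_strand_4, start: 112, end: 114, kind: basic_strand}
  IL34:
    uniprot: Q6ZMJ4
    signal_peptide: {start: 1, end: 20}
    regions:
      - {name: helix2_region, start: 71, end: 85, kind: candidate_region}
      - {name: helix3_region, start: 90, end: 100, kind: candidate_region}
      - {name: helix4_region, start: 119, end: 129, kind: candidate_region}
      - {name: helix5_region, start: 142, end: 151, kind: candidate_region}
      - {name: helix6_region, start: 156, end: 179, kind: candidate_region}
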