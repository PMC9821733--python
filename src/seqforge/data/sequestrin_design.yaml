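# Default sequestrin library design.
#
# The scaffold gene is the assembled 321-nt library oligo (fixed codons
# verbatim; the 22 randomized codons written as NNN).  Eleven positions per
# subunit are diversified, with identical distributions in both subunits:
#   - 9 spiked positions per subunit keep the wildtype codon at 61% mixed with
#     39% mutation codons from a class alphabet (beta-strand: all residues but
#     Cys; hydrophobic-core: AVILMFW; spiked/surface: all but Pro/Gly/Cys),
#   - 2 positions per subunit toggle 50:50 between wildtype and one alternative.
#
# The per-position class membership, wildtype residues and binary alternatives
# below are a synthetic reconstruction (the published design figure is not
# machine-readable); they are class-compatible choices whose combinatorics
# reproduce the design-level numbers.  Fixed codons are exactly as printed.
scaffold:
  gene: |
    GCGGGTGGCGAANNNNNNNNNNNNCCGAACTTANNNNNNGACCAANNNTGTGCCNNNNNN
    CGTAGTNNNGAAGATGATCCTAGTCAAAGCGCTAACTTGNNNGCAGAAGCTAAAAAGCTA
    AATGATGCTCAGGCGCCGGCGAGCAGCAGCAGCGGGAGCAGCAGCAGCGGGCGCGCGAGT
    GCGGGTGGCGAGNNNNNNNNNNNNCCGAACTTANNNNNNGACCAANNNTGTGCCNNNNNN
    CGTAGTNNNGAGGATGACCCTAGTCAAAGCGCTAACTTGNNNGCAGAAGCTAAAAAGCTA
    AATGATGCTCAGGCGCCGAAA
  subunit_length: 46
  cys_position: 17
codon_policy: ecoli-most-frequent
spiked_wildtype_fraction: 0.61
positions:
  - {subunit: 1, position: 5,  wildtype: E, class: beta-strand}
  - {subunit: 1, position: 6,  wildtype: I, class: beta-strand}
  - {subunit: 1, position: 7,  wildtype: V, class: beta-strand}
  - {subunit: 1, position: 8,  wildtype: S, class: binary, alternative: T}
  - {subunit: 1, position: 12, wildtype: N, class: spiked}
  - {subunit: 1, position: 13, wildtype: E, class: spiked}
  - {subunit: 1, position: 16, wildtype: R, class: spiked}
  - {subunit: 1, position: 19, wildtype: L, class: hydrophobic-core}
  - {subunit: 1, position: 20, wildtype: A, class: spiked}
  - {subunit: 1, position: 23, wildtype: K, class: binary, alternative: R}
  - {subunit: 1, position: 34, wildtype: L, class: hydrophobic-core}
  - {subunit: 2, position: 5,  wildtype: E, class: beta-strand}
  - {subunit: 2, position: 6,  wildtype: I, class: beta-strand}
  - {subunit: 2, position: 7,  wildtype: V, class: beta-strand}
  - {subunit: 2, position: 8,  wildtype: S, class: binary, alternative: T}
  - {subunit: 2, position: 12, wildtype: N, class: spiked}
  - {subunit: 2, position: 13, wildtype: E, class: spiked}
  - {subunit: 2, position: 16, wildtype: R, class: spiked}
  - {subunit: 2, position: 19, wildtype: L, class: hydrophobic-core}
  - {subunit: 2, position: 20, wildtype: A, class: spiked}
  - {subunit: 2, position: 23, wildtype: K, class: binary, alternative: R}
  - {subunit: 2, position: 34, wildtype: L, class: hydrophobic-core}
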