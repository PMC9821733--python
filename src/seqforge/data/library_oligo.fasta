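>sequestrin_library_gene assembled 321-nt degenerate library oligo (NNN at the 22 randomized codons)
GCGGGTGGCGAANNNNNNNNNNNNCCGAACTTANNNNNNGACCAANNNTGTGCCNNNNNN
CGTAGTNNNGAAGATGATCCTAGTCAAAGCGCTAACTTGNNNGCAGAAGCTAAAAAGCTA
AATGATGCTCAGGCGCCGGCGAGCAGCAGCAGCGGGAGCAGCAGCAGCGGGCGCGCGAGT
GCGGGTGGCGAGNNNNNNNNNNNNCCGAACTTANNNNNNGACCAANNNTGTGCCNNNNNN
CGTAGTNNNGAGGATGACCCTAGTCAAAGCGCTAACTTGNNNGCAGAAGCTAAAAAGCTA
AATGATGCTCAGGCGCCGAAA
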