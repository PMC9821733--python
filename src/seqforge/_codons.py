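"""Codon tables and small translation helpers shared across modules."""

from __future__ import annotations

from Bio.Seq import Seq

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Most frequently used codon per amino acid in the E. coli K-12 genome.
ECOLI_PREFERRED = {
    "A": "GCG", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGC",
    "E": "GAA", "Q": "CAG", "G": "GGC", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTG",
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: full 64-codon lookup, stops as '*'
CODON_TABLE = {
    a + b + c: str(Seq(a + b + c).translate())
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
}


def codons_of(dna: str) -> list[str]:
    """Split a frame-0 sequence into codons (trailing partial codon dropped)."""
    return [dna[i:i + 3] for i in range(0, len(dna) - len(dna) % 3, 3)]


def translate(dna: str) -> str:
    """Frame-0 translation; degenerate codons containing N become 'X'."""
    return "".join(CODON_TABLE.get(codon, "X") for codon in codons_of(dna))


def printed_codon_usage(gene: str) -> dict[str, str]:
    """First codon observed per residue in the fixed part of a template gene.

    Used by the match-printed-oligo codon policy: residues keep the synonymous
    codon the synthesized oligo actually used where one is available.
    """
    usage: dict[str, str] = {}
    for codon in codons_of(gene):
        if "N" in codon or codon in STOP_CODONS:
            continue
        aa = str(Seq(codon).translate())
        usage.setdefault(aa, codon)
    return usage
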