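"""Shared sequence primitives: alphabets, codon table, translation helpers.

A single fixed one-codon-per-amino-acid table is used for reverse
translation throughout the package so that six-frame recovery of coding
sequences is exact and deterministic.
"""
from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)
NT_ALPHABET = "ACGT"
STOP = "*"

#: fixed reverse-translation table (one codon per amino acid); L and S use
#: codons whose reverse complements are stop codons (TAA, TGA) so that
#: antisense frames of simulated coding sequences terminate quickly
CODON_FOR_AA = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "TTA", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCA", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}
STOP_CODON = "TAA"

# full forward table (all 64 codons) for translation of arbitrary frames
_FORWARD = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _FORWARD[_stop] = STOP


def reverse_translate(protein: str) -> str:
    """Coding sequence for *protein* under the fixed codon table, with a
    terminal stop codon."""
    try:
        return "".join(CODON_FOR_AA[aa] for aa in protein) + STOP_CODON
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"not an amino acid: {exc.args[0]!r}") from exc


def translate_frame(nt: str, offset: int) -> str:
    """Translate ``nt`` starting at ``offset``; non-ACGT codons and stop
    codons both yield ``*`` (conservative: unknown bases break ORFs)."""
    out = []
    for i in range(offset, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        out.append(_FORWARD.get(codon, STOP))
    return "".join(out)


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def validate_protein(seq: str) -> None:
    bad = set(seq) - AA_SET
    if bad:
        raise ValueError(f"invalid amino-acid character(s): {sorted(bad)}")
    if not seq:
        raise ValueError("empty protein sequence")
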