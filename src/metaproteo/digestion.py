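"""In-silico tryptic digestion and pseudo-reversal of protein sequences.

Cleavage rule: C-terminal to K or R, except when the next residue is P.
"""
from __future__ import annotations

from ._seq import AA_SET


def cleavage_sites(sequence: str) -> list[int]:
    """Positions *after* which the chain is cut (0-based index of the K/R)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def cleavage_fragments(sequence: str) -> list[str]:
    """Fully cleaved (zero missed cleavages) products, in order.

    Concatenating the fragments reconstructs the sequence.
    """
    frags = []
    start = 0
    for site in cleavage_sites(sequence):
        frags.append(sequence[start : site + 1])
        start = site + 1
    if start < len(sequence):
        frags.append(sequence[start:])
    return frags


def digest(
    sequence: str,
    max_missed_cleavages: int = 2,
    min_len: int = 6,
    max_len: int = 40,
) -> set[str]:
    """All tryptic products of ``sequence`` with at most
    ``max_missed_cleavages`` internal uncut sites and length within
    ``[min_len, max_len]``."""
    if not 0 <= max_missed_cleavages <= 3:
        raise ValueError("max_missed_cleavages must be in [0, 3]")
    if not 1 <= min_len <= max_len:
        raise ValueError("need 1 <= min_len <= max_len")
    bad = set(sequence) - AA_SET
    if bad or not sequence:
        raise ValueError(f"invalid amino-acid character(s): {sorted(bad)}")
    frags = cleavage_fragments(sequence)
    out: set[str] = set()
    for i in range(len(frags)):
        pep = ""
        for j in range(i, min(i + max_missed_cleavages + 1, len(frags))):
            pep += frags[j]
            if min_len <= len(pep) <= max_len:
                out.add(pep)
            elif len(pep) > max_len:
                break
    return out


def ordered_peptides(
    sequence: str, min_len: int = 6, max_len: int = 40
) -> list[str]:
    """Zero-missed-cleavage products within the length bounds, kept in
    positional order (used for marker construction)."""
    return [p for p in cleavage_fragments(sequence) if min_len <= len(p) <= max_len]


def pseudo_reverse(sequence: str) -> str:
    """Decoy sequence: each tryptic segment is reversed while its terminal
    K/R stays in place, preserving the tryptic peptide-length multiset."""
    out = []
    for frag in cleavage_fragments(sequence):
        if frag and frag[-1] in "KR":
            out.append(frag[:-1][::-1] + frag[-1])
        else:
            out.append(frag[::-1])
    return "".join(out)
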