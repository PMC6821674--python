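"""Taxonomic LCA and consensus functional annotation of protein groups.

Each accepted group's anchor sequence is locally aligned (Smith-Waterman,
BLOSUM62, gap open 11 / extend 1) against the annotated reference store;
the up-to-20 hits with bit score > 80 drive both the lowest common
ancestor and the modal-name consensus (> 80% agreement).
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .search import ProteinGroup, SearchResult
from .simulate import ReferenceProteinRecord
from .taxonomy import RANK_DEPTH, RANKS, TaxonomyTree

# gapped Karlin-Altschul constants for BLOSUM62 11/1
_LAMBDA = 0.267
_K = 0.041
_LN2 = math.log(2.0)

_aligner = Align.PairwiseAligner()
_aligner.mode = "local"
_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
# "gap open 11, extend 1": a gap of length L costs 11 + L
_aligner.open_gap_score = -12.0
_aligner.extend_gap_score = -1.0


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    taxon_id: str
    function_name: str


@dataclass(frozen=True)
class TaxonomicAnnotation:
    taxon_id: Optional[str]
    rank: Optional[str]
    n_hits_used: int


@dataclass(frozen=True)
class FunctionalAnnotation:
    name: Optional[str]
    agreement: float
    needs_manual: bool


@dataclass
class AnnotatedMetaproteome:
    result: SearchResult
    taxonomic: dict[str, TaxonomicAnnotation]    # keyed by group_id
    functional: dict[str, FunctionalAnnotation]


def bit_score(raw_score: float) -> float:
    return (_LAMBDA * raw_score - math.log(_K)) / _LN2


def local_align(query: str, subject: str, query_id: str = "query",
                record: Optional[ReferenceProteinRecord] = None) -> AlignmentHit:
    """Smith-Waterman local alignment score plus derived bit score."""
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    raw = float(_aligner.score(query, subject))
    raw = max(raw, 0.0)
    return AlignmentHit(
        query_id=query_id,
        subject_id=record.protein_id if record else "subject",
        raw_score=raw,
        bit_score=bit_score(raw),
        taxon_id=record.taxon_id if record else "",
        function_name=record.function_name if record else "",
    )


def _kmers(seq: str, k: int = 5) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def top_hits(
    query_group: ProteinGroup,
    refdb: list[ReferenceProteinRecord],
    max_hits: int = 20,
    min_bitscore: float = 80.0,
    *,
    query_sequence: Optional[str] = None,
    prefilter: bool = True,
    prefilter_top: int = 200,
) -> list[AlignmentHit]:
    """Up to ``max_hits`` reference hits with bit score > ``min_bitscore``,
    sorted by bit score descending (ties by subject id).

    Candidates are prefiltered to the ``prefilter_top`` references sharing
    the most 5-mers with the query; ``prefilter=False`` aligns against the
    whole store and is the test oracle.
    """
    if not refdb:
        raise ValueError("empty reference store")
    if query_sequence is None:
        raise ValueError("query_sequence (anchor sequence) is required")
    candidates = sorted(refdb, key=lambda r: r.protein_id)
    if prefilter and len(candidates) > prefilter_top:
        qk = _kmers(query_sequence)
        scored = [(-len(qk & _kmers(r.sequence)), r.protein_id, r)
                  for r in candidates]
        scored.sort(key=lambda t: (t[0], t[1]))
        candidates = [r for _, _, r in scored[:prefilter_top]]
    hits = []
    for rec in candidates:
        hit = local_align(query_sequence, rec.sequence,
                          query_id=query_group.group_id, record=rec)
        if hit.bit_score > min_bitscore:
            hits.append(hit)
    hits.sort(key=lambda h: (-h.bit_score, h.subject_id))
    return hits[:max_hits]


def lca_annotate(hits: list[AlignmentHit],
                 tree: TaxonomyTree) -> TaxonomicAnnotation:
    """Deepest taxonomy node that is ancestor-or-self of every hit taxon."""
    if not hits:
        return TaxonomicAnnotation(None, None, 0)
    taxa = []
    for h in hits:
        if h.taxon_id not in tree:
            raise KeyError(f"unresolvable taxon {h.taxon_id!r}")
        taxa.append(h.taxon_id)
    node = tree.lca(taxa)
    return TaxonomicAnnotation(node.taxon_id, node.rank, len(hits))


_DESIGNATOR_HEADS = {"subunit", "chain", "isoform"}
_GREEK = {"alpha", "beta", "gamma", "delta", "epsilon"}


def normalize_function_name(name: str) -> str:
    """Lowercase and strip trailing subunit/isoform/chain designators and
    bare numeric or Greek-letter suffixes, so isoforms and sub-units of one
    protein share a function label."""
    tokens = re.sub(r"\s+", " ", name.strip().lower()).split(" ")
    while tokens:
        last = tokens[-1]
        if len(tokens) >= 2 and tokens[-2] in _DESIGNATOR_HEADS:
            tokens = tokens[:-2]
        elif last in _GREEK or last.isdigit():
            tokens = tokens[:-1]
        else:
            break
    return " ".join(tokens)


def consensus_function(hits: list[AlignmentHit],
                       tolerance: float = 0.8) -> FunctionalAnnotation:
    """Modal normalized name among the hits; accepted when its frequency
    strictly exceeds ``tolerance``, otherwise flagged for manual review."""
    if not 0 < tolerance < 1:
        raise ValueError("tolerance must be in (0, 1)")
    if not hits:
        return FunctionalAnnotation(None, 0.0, False)
    counts: dict[str, int] = {}
    for h in hits:
        key = normalize_function_name(h.function_name)
        counts[key] = counts.get(key, 0) + 1
    modal = min(
        (name for name, c in counts.items() if c == max(counts.values())))
    agreement = counts[modal] / len(hits)
    if agreement > tolerance:
        return FunctionalAnnotation(modal, agreement, False)
    return FunctionalAnnotation(None, agreement, True)


def annotate_group(
    group: ProteinGroup,
    anchor_sequence: str,
    refdb: list[ReferenceProteinRecord],
    tree: TaxonomyTree,
    max_hits: int = 20,
    min_bitscore: float = 80.0,
    tolerance: float = 0.8,
    prefilter: bool = True,
    prefilter_top: int = 200,
) -> tuple[TaxonomicAnnotation, FunctionalAnnotation]:
    hits = top_hits(group, refdb, max_hits, min_bitscore,
                    query_sequence=anchor_sequence, prefilter=prefilter,
                    prefilter_top=prefilter_top)
    return lca_annotate(hits, tree), consensus_function(hits, tolerance)


def annotate_all(
    result: SearchResult,
    anchor_sequences: dict[str, str],
    refdb: list[ReferenceProteinRecord],
    tree: TaxonomyTree,
    max_hits: int = 20,
    min_bitscore: float = 80.0,
    tolerance: float = 0.8,
    prefilter: bool = True,
    prefilter_top: int = 200,
    cache: Optional[dict] = None,
) -> AnnotatedMetaproteome:
    """Annotate every accepted group of ``result``.

    ``anchor_sequences`` maps group_id -> anchor member sequence. ``cache``
    (keyed by anchor sequence) lets callers reuse annotations across
    metaproteomes that share anchors.
    """
    taxonomic: dict[str, TaxonomicAnnotation] = {}
    functional: dict[str, FunctionalAnnotation] = {}
    for group in result.groups:
        seq = anchor_sequences[group.group_id]
        if cache is not None and seq in cache:
            tax, func = cache[seq]
        else:
            tax, func = annotate_group(
                group, seq, refdb, tree, max_hits, min_bitscore, tolerance,
                prefilter, prefilter_top)
            if cache is not None:
                cache[seq] = (tax, func)
        taxonomic[group.group_id] = tax
        functional[group.group_id] = func
    return AnnotatedMetaproteome(result, taxonomic, functional)


def annotation_fractions(am: AnnotatedMetaproteome) -> dict[str, float]:
    """Per-rank fraction of accepted groups annotated at that rank or
    deeper (0.0 by convention for an empty result)."""
    n = len(am.result.groups)
    fractions = {}
    for rank in RANKS:
        if n == 0:
            fractions[rank] = 0.0
            continue
        depth = RANK_DEPTH[rank]
        count = sum(
            1 for t in am.taxonomic.values()
            if t.rank is not None and RANK_DEPTH[t.rank] >= depth)
        fractions[rank] = count / n
    return fractions


def anchor_sequence_map(result: SearchResult, db) -> dict[str, str]:
    """group_id -> anchor entry sequence for every accepted group."""
    return {g.group_id: db.entries[g.anchor_entry_id].sequence
            for g in result.groups}
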