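"""Construction of the four protein search databases from one metagenome.

Strategies:

* NAM — genes predicted directly from (trimmed) reads by six-frame
  stop-free ORF extraction, no start codon required.
* AM  — reads greedily assembled by exact suffix/prefix overlap into
  contigs, then the same ORF extraction on the contigs.
* TAX — genera detected from marker k-mers, then the full reference
  proteome of every detected genus.
* Comb — union of second-round databases, deduplicated, fresh decoys.
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable

from . import digestion
from ._seq import revcomp, translate_frame
from .simulate import Read, ReadSet, ReferenceProteinRecord

DB_NAMES = ("NAM", "AM", "TAX", "Comb")


@dataclass(frozen=True)
class DBEntry:
    entry_id: str
    sequence: str
    origin: str = ""


@dataclass
class ProteinDB:
    db_name: str
    round: int
    entries: dict[str, DBEntry] = field(default_factory=dict)
    decoy_entries: dict[str, DBEntry] = field(default_factory=dict)

    def __post_init__(self):
        if self.db_name not in DB_NAMES:
            raise ValueError(f"db_name must be one of {DB_NAMES}")
        if self.round not in (1, 2):
            raise ValueError("round must be 1 or 2")
        overlap = set(self.entries) & set(self.decoy_entries)
        if overlap:
            raise ValueError(f"entry ids shared with decoys: {sorted(overlap)[:3]}")

    def __len__(self):
        return len(self.entries)

    def add(self, entry: DBEntry) -> None:
        if entry.entry_id in self.entries:
            raise ValueError(f"duplicate entry_id {entry.entry_id!r}")
        self.entries[entry.entry_id] = entry

    @property
    def target_sequences(self) -> set[str]:
        return {e.sequence for e in self.entries.values()}


@dataclass(frozen=True)
class Contig:
    contig_id: str
    sequence: str
    support: int  # number of reads merged

    def __post_init__(self):
        if self.support < 1:
            raise ValueError("support must be >= 1")


@dataclass(frozen=True)
class GeneFragment:
    source_id: str
    frame: int           # 0-2
    strand: str          # '+' or '-'
    aa_start: int        # 0-based half-open on the translated frame
    aa_end: int
    sequence: str


# ---------------------------------------------------------------------------
# read trimming
# ---------------------------------------------------------------------------

def trim_reads(reads: ReadSet, min_mean_quality: float = 20.0,
               min_length: int = 30, window: int = 4) -> ReadSet:
    """3'-trim each read at the start of the first sliding window (size 4,
    step 1) whose mean quality falls below the threshold, then drop reads
    shorter than ``min_length``. Order is preserved."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    out = []
    for read in reads:
        q = read.qualities
        cut = len(q)
        for i in range(0, len(q) - window + 1):
            if sum(q[i : i + window]) / window < min_mean_quality:
                cut = i
                break
        if cut >= min_length:
            out.append(Read(read.read_id, read.sequence[:cut],
                            read.qualities[:cut], read.source))
    return ReadSet(out)


# ---------------------------------------------------------------------------
# gene prediction (six-frame stop-free ORFs)
# ---------------------------------------------------------------------------

def extract_orfs(sequence: str, source_id: str, min_orf_aa: int) -> list[GeneFragment]:
    """Maximal stop-free amino-acid stretches of length >= ``min_orf_aa``
    over all six frames; edge-truncated stretches are kept (no start codon
    required). Non-ACGT codons act as stops."""
    frags = []
    for strand, nt in (("+", sequence), ("-", revcomp(sequence))):
        for frame in range(3):
            aa = translate_frame(nt, frame)
            start = 0
            for i, ch in enumerate(aa + "*"):
                if ch == "*":
                    if i - start >= min_orf_aa:
                        frags.append(GeneFragment(
                            source_id=source_id, frame=frame, strand=strand,
                            aa_start=start, aa_end=i, sequence=aa[start:i]))
                    start = i + 1
    return frags


def _orfs_to_db(sources: Iterable[tuple[str, str]], db_name: str,
                min_orf_aa: int) -> ProteinDB:
    if min_orf_aa < 5:
        raise ValueError("min_orf_aa must be >= 5")
    db = ProteinDB(db_name=db_name, round=1)
    for source_id, seq in sources:
        for frag in extract_orfs(seq, source_id, min_orf_aa):
            eid = (f"{source_id}|{frag.strand}{frag.frame}"
                   f"|{frag.aa_start}-{frag.aa_end}")
            db.add(DBEntry(eid, frag.sequence, origin=f"orf:{source_id}"))
    return db


def predict_genes_from_reads(reads: ReadSet, min_orf_aa: int = 20) -> ProteinDB:
    """NAM round-1 database from six-frame ORFs of every read."""
    return _orfs_to_db(((r.read_id, r.sequence) for r in reads),
                       "NAM", min_orf_aa)


def predict_genes_from_contigs(contigs: Iterable[Contig],
                               min_orf_aa: int = 20) -> ProteinDB:
    """AM round-1 database from six-frame ORFs of the contigs."""
    return _orfs_to_db(((c.contig_id, c.sequence) for c in contigs),
                       "AM", min_orf_aa)


# ---------------------------------------------------------------------------
# greedy overlap assembly
# ---------------------------------------------------------------------------

def _best_overlap(a: str, b: str, min_overlap: int) -> int:
    """Longest exact suffix(a)/prefix(b) overlap >= min_overlap, else 0."""
    mo = min_overlap
    best = 0
    for ov in range(min(len(a), len(b)), mo - 1, -1):
        if a[-ov:] == b[:ov]:
            best = ov
            break
    return best


def assemble_reads(reads: ReadSet, min_overlap: int = 25) -> list[Contig]:
    """Greedy overlap-layout assembly.

    Repeatedly merges the pair with the longest exact suffix-prefix overlap
    >= ``min_overlap`` (both orientations considered; ties broken
    lexicographically by (id, orientation) pairs) until no merge is
    possible. Unmerged reads come back as singleton contigs.
    """
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    mo = min_overlap

    seqs: dict[str, tuple[str, str]] = {}   # id -> (forward, revcomp)
    support: dict[str, int] = {}
    for r in reads:
        seqs[r.read_id] = (r.sequence, revcomp(r.sequence))
        support[r.read_id] = 1

    # prefix_index: k-mer -> (id, orient) whose oriented prefix is the k-mer
    # suffix_index: k-mer -> (id, orient, ov): the k-mer starts the length-ov
    #   suffix of the oriented sequence (every position is indexed)
    prefix_index: dict[str, list[tuple[str, str]]] = {}
    suffix_index: dict[str, list[tuple[str, str, int]]] = {}
    alive: set[str] = set()
    heap: list[tuple[int, str, str, str, str, int]] = []

    def oriented(sid: str, orient: str) -> str:
        fwd, rc = seqs[sid]
        return fwd if orient == "F" else rc

    def register(sid: str) -> None:
        for orient in ("F", "R"):
            s = oriented(sid, orient)
            if len(s) < mo:
                continue
            prefix_index.setdefault(s[:mo], []).append((sid, orient))
            for p in range(len(s) - mo + 1):
                suffix_index.setdefault(s[p : p + mo], []).append(
                    (sid, orient, len(s) - p))

    def push_as_left(sid: str) -> None:
        for orient in ("F", "R"):
            a = oriented(sid, orient)
            for p in range(max(0, len(a) - mo), -1, -1):
                ov = len(a) - p
                for other, o2 in prefix_index.get(a[p : p + mo], ()):
                    if other == sid or other not in alive:
                        continue
                    b = oriented(other, o2)
                    if ov <= len(b) and a[p:] == b[:ov]:
                        heapq.heappush(heap, (-ov, sid, orient, other, o2, ov))

    def push_as_right(sid: str) -> None:
        for orient in ("F", "R"):
            b = oriented(sid, orient)
            if len(b) < mo:
                continue
            for other, o2, ov in suffix_index.get(b[:mo], ()):
                if other == sid or other not in alive:
                    continue
                a = oriented(other, o2)
                if ov <= len(b) and a[-ov:] == b[:ov]:
                    heapq.heappush(heap, (-ov, other, o2, sid, orient, ov))

    for sid in sorted(seqs):
        alive.add(sid)
        register(sid)
    for sid in sorted(seqs):
        push_as_left(sid)

    counter = 0
    while heap:
        _, sid_a, oa, sid_b, ob, ov = heapq.heappop(heap)
        if sid_a not in alive or sid_b not in alive or sid_a == sid_b:
            continue
        a = oriented(sid_a, oa)
        b = oriented(sid_b, ob)
        if ov > min(len(a), len(b)) or a[-ov:] != b[:ov]:
            continue  # stale entry
        merged = a + b[ov:]
        counter += 1
        new_id = f"ctg{counter:06d}"
        alive.discard(sid_a)
        alive.discard(sid_b)
        seqs[new_id] = (merged, revcomp(merged))
        support[new_id] = support[sid_a] + support[sid_b]
        alive.add(new_id)
        register(new_id)
        push_as_left(new_id)
        push_as_right(new_id)

    contigs = []
    for i, sid in enumerate(sorted(alive)):
        contigs.append(Contig(contig_id=f"contig{i:06d}",
                              sequence=seqs[sid][0], support=support[sid]))
    return contigs


# ---------------------------------------------------------------------------
# taxon detection and TAX database
# ---------------------------------------------------------------------------

def build_marker_index(
    proteomes: list[ReferenceProteinRecord],
    n_marker_proteins: int = 5,
    n_peptides: int = 10,
    k: int = 21,
) -> dict[str, set[str]]:
    """Genus -> marker k-mers taken from the coding sequences of the first
    ``n_peptides`` tryptic peptides of the first ``n_marker_proteins``
    proteins (by id) of each genus. Arbitrary but fixed."""
    from ._seq import reverse_translate

    by_genus: dict[str, list[ReferenceProteinRecord]] = {}
    for rec in proteomes:
        by_genus.setdefault(rec.taxon_id, []).append(rec)
    index: dict[str, set[str]] = {}
    for genus, recs in sorted(by_genus.items()):
        kmers: set[str] = set()
        for rec in sorted(recs, key=lambda r: r.protein_id)[:n_marker_proteins]:
            for pep in digestion.ordered_peptides(rec.sequence)[:n_peptides]:
                nt = reverse_translate(pep)[:-3]  # drop terminal stop codon
                for i in range(len(nt) - k + 1):
                    kmers.add(nt[i : i + k])
        index[genus] = kmers
    return index


def detect_taxa(reads: ReadSet, marker_index: dict[str, set[str]],
                min_hits: int = 5) -> set[str]:
    """Genera whose marker k-mers occur (either strand) in at least
    ``min_hits`` reads."""
    if not marker_index or all(not v for v in marker_index.values()):
        raise ValueError("empty marker index")
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    k = len(next(iter(next(v for v in marker_index.values() if v))))
    kmer_to_genera: dict[str, set[str]] = {}
    for genus, kmers in marker_index.items():
        for km in kmers:
            kmer_to_genera.setdefault(km, set()).add(genus)
    counts: dict[str, int] = {}
    for read in reads:
        hit_genera: set[str] = set()
        for seq in (read.sequence, revcomp(read.sequence)):
            for i in range(len(seq) - k + 1):
                g = kmer_to_genera.get(seq[i : i + k])
                if g:
                    hit_genera |= g
        for genus in hit_genera:
            counts[genus] = counts.get(genus, 0) + 1
    return {g for g, c in counts.items() if c >= min_hits}


def build_taxonomy_db(detected: set[str],
                      proteome_store: list[ReferenceProteinRecord]) -> ProteinDB:
    """TAX round-1 database: every reference protein of every detected
    genus (full proteomes, not just expressed proteins), deduplicated."""
    known = {rec.taxon_id for rec in proteome_store}
    unknown = detected - known
    if unknown:
        raise KeyError(f"unknown genus id(s): {sorted(unknown)}")
    db = ProteinDB(db_name="TAX", round=1)
    for rec in sorted(proteome_store, key=lambda r: r.protein_id):
        if rec.taxon_id in detected:
            db.add(DBEntry(rec.protein_id, rec.sequence,
                           origin=f"taxon={rec.taxon_id}"))
    return deduplicate(db)


# ---------------------------------------------------------------------------
# deduplication, decoys, merging
# ---------------------------------------------------------------------------

def deduplicate(db: ProteinDB) -> ProteinDB:
    """Collapse exact duplicate target sequences, keeping the
    lexicographically smallest entry_id. Idempotent. Decoys are dropped
    (they are rebuilt from the deduplicated targets)."""
    keeper: dict[str, DBEntry] = {}
    for entry in sorted(db.entries.values(), key=lambda e: e.entry_id):
        if entry.sequence not in keeper:
            keeper[entry.sequence] = entry
    out = ProteinDB(db_name=db.db_name, round=db.round)
    for entry in sorted(keeper.values(), key=lambda e: e.entry_id):
        out.add(entry)
    return out


def build_decoys(db: ProteinDB) -> ProteinDB:
    """One pseudo-reversed decoy per target (``DECOY_`` id prefix); returns
    a new database with both partitions."""
    out = ProteinDB(db_name=db.db_name, round=db.round,
                    entries=dict(db.entries))
    for entry in db.entries.values():
        out.decoy_entries[f"DECOY_{entry.entry_id}"] = DBEntry(
            f"DECOY_{entry.entry_id}",
            digestion.pseudo_reverse(entry.sequence),
            origin=f"decoy_of={entry.entry_id}",
        )
    return out


def merge_dbs(dbs: list[ProteinDB], name: str = "Comb",
              round: int = 2, with_decoys: bool = True) -> ProteinDB:
    """Union of target entries of ``dbs``, deduplicated; decoys rebuilt
    fresh from the merged targets (never carried over)."""
    if not dbs:
        raise ValueError("need at least one database to merge")
    merged = ProteinDB(db_name=name, round=round)
    for db in dbs:
        for entry in sorted(db.entries.values(), key=lambda e: e.entry_id):
            eid = entry.entry_id
            if eid in merged.entries:
                if merged.entries[eid].sequence == entry.sequence:
                    continue
                eid = f"{db.db_name}:{eid}"
            merged.add(DBEntry(eid, entry.sequence, entry.origin))
    merged = deduplicate(merged)
    return build_decoys(merged) if with_decoys else merged


# ---------------------------------------------------------------------------
# pipeline conveniences
# ---------------------------------------------------------------------------

def build_nam_db(reads: ReadSet, min_orf_aa: int = 20) -> ProteinDB:
    return deduplicate(predict_genes_from_reads(reads, min_orf_aa))


def build_am_db(reads: ReadSet, min_overlap: int = 25, min_orf_aa: int = 20,
                drop_singletons: bool = True) -> ProteinDB:
    """Assemble then predict. ``drop_singletons`` (default on, mirroring
    real assemblers' minimum-contig behaviour) discards contigs supported
    by a single read — the source of the NAM > AM contrast."""
    contigs = assemble_reads(reads, min_overlap)
    if drop_singletons:
        contigs = [c for c in contigs if c.support >= 2]
    return deduplicate(predict_genes_from_contigs(contigs, min_orf_aa))
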