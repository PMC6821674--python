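"""Plain-text readers and writers: FASTA, FASTQ, and the TSV formats.

Everything round-trips losslessly on canonical form. Database FASTA
headers follow ``>{db}|{round}|{entry_id} origin=...``; decoy entries keep
their ``DECOY_`` id prefix.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dbbuild import DBEntry, ProteinDB
from .simulate import ObservedPeptidome, Read, ReadSet
from .taxonomy import TaxNode, TaxonomyTree

PathLike = Union[str, Path]


class DataError(ValueError):
    """Malformed input data (exit code 3 at the CLI)."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(records: Iterable[tuple[str, str]], path: PathLike,
                width: int = 70) -> None:
    """``records`` are (header, sequence) pairs; header is written verbatim
    after '>'."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: PathLike) -> list[tuple[str, str]]:
    """(full header, sequence) pairs."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.description, str(rec.seq)))
    return out


def write_protein_db(db: ProteinDB, path: PathLike) -> None:
    records = []
    for entry in sorted(db.entries.values(), key=lambda e: e.entry_id):
        records.append((f"{db.db_name}|{db.round}|{entry.entry_id} "
                        f"origin={entry.origin}", entry.sequence))
    for entry in sorted(db.decoy_entries.values(), key=lambda e: e.entry_id):
        records.append((f"{db.db_name}|{db.round}|{entry.entry_id} "
                        f"origin={entry.origin}", entry.sequence))
    write_fasta(records, path)


def read_protein_db(path: PathLike) -> ProteinDB:
    records = read_fasta(path)
    if not records:
        raise DataError(f"empty database FASTA: {path}")
    db = None
    for lineno, (header, seq) in enumerate(records, start=1):
        head = header.split(" ", 1)
        parts = head[0].split("|")
        if len(parts) != 3:
            raise DataError(
                f"{path}: record {lineno}: header {head[0]!r} does not "
                f"follow db|round|entry_id")
        db_name, rnd, entry_id = parts
        origin = ""
        if len(head) > 1 and head[1].startswith("origin="):
            origin = head[1][len("origin="):]
        if db is None:
            db = ProteinDB(db_name=db_name, round=int(rnd))
        entry = DBEntry(entry_id, seq, origin)
        if entry_id.startswith("DECOY_"):
            db.decoy_entries[entry_id] = entry
        else:
            db.add(entry)
    return db


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def write_fastq(reads: ReadSet, path: PathLike) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: PathLike) -> ReadSet:
    reads = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            reads.append(Read(
                read_id=rec.id,
                sequence=str(rec.seq),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
            ))
    except ValueError as exc:
        raise DataError(f"{path}: malformed FASTQ: {exc}") from exc
    return ReadSet(reads)


# ---------------------------------------------------------------------------
# taxonomy TSV (topology + names)
# ---------------------------------------------------------------------------

def write_taxonomy(tree: TaxonomyTree, path: PathLike,
                   names_path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["taxon_id", "parent_id", "rank"])
        for tid in sorted(tree.nodes):
            n = tree.nodes[tid]
            w.writerow([n.taxon_id, n.parent_id or "", n.rank])
    with open(names_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["taxon_id", "name"])
        for tid in sorted(tree.nodes):
            w.writerow([tid, tree.nodes[tid].name])


def read_taxonomy(path: PathLike, names_path: PathLike) -> TaxonomyTree:
    names: dict[str, str] = {}
    with open(names_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            names[row["taxon_id"]] = row["name"]
    nodes = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh, delimiter="\t"), 2):
            tid = row["taxon_id"]
            nodes.append(TaxNode(
                taxon_id=tid,
                name=names.get(tid, tid),
                rank=row["rank"],
                parent_id=row["parent_id"] or None,
            ))
    try:
        return TaxonomyTree(nodes)
    except ValueError as exc:
        raise DataError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# peptidome TSV (+ truth)
# ---------------------------------------------------------------------------

def write_peptidome(pep: ObservedPeptidome, path: PathLike,
                    truth_path: PathLike | None = None) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["peptide", "count"])
        for p in sorted(pep.observations):
            w.writerow([p, pep.observations[p]])
    if truth_path is not None:
        with open(truth_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["peptide", "sources"])
            for p in sorted(pep.truth):
                srcs = sorted(pep.truth[p])
                w.writerow([p, ";".join(srcs) if srcs else "noise"])


def read_peptidome(path: PathLike, label: str,
                   truth_path: PathLike | None = None) -> ObservedPeptidome:
    observations: dict[str, int] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh, delimiter="\t"), 2):
            try:
                observations[row["peptide"]] = int(row["count"])
            except (KeyError, TypeError, ValueError) as exc:
                raise DataError(f"{path}: line {lineno}: {exc}") from exc
    truth: dict[str, frozenset[str]] = {}
    if truth_path is not None:
        with open(truth_path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                srcs = row["sources"]
                truth[row["peptide"]] = (
                    frozenset() if srcs == "noise" else
                    frozenset(srcs.split(";")))
    else:
        truth = {p: frozenset() for p in observations}
    return ObservedPeptidome(label=label, observations=observations,
                             truth=truth)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_search_result(result, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["group_id", "anchor", "members", "n_distinct_peptides",
                    "n_spectra", "score", "decoy_flag", "accepted_flag"])
        for g in result.groups:
            w.writerow([g.group_id, g.anchor_entry_id,
                        ";".join(g.member_entry_ids),
                        g.n_distinct_peptides, g.n_spectra, g.score,
                        int(g.is_decoy), 1])


def write_annotations(am, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["group_id", "lca_taxon", "lca_rank", "function_name",
                    "agreement", "needs_manual"])
        for g in am.result.groups:
            tax = am.taxonomic[g.group_id]
            func = am.functional[g.group_id]
            w.writerow([g.group_id, tax.taxon_id or "", tax.rank or "",
                        func.name or "", f"{func.agreement:.4f}",
                        int(func.needs_manual)])


def write_distribution(table, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["label", "proportion_percent"])
        for label, prop in table.rows.items():
            w.writerow([label, f"{prop:.4f}"])


def write_proteomes_fasta(proteomes, path: PathLike) -> None:
    records = [
        (f"{rec.protein_id} taxon={rec.taxon_id} family={rec.family_id} "
         f"function={rec.function_name}", rec.sequence)
        for rec in sorted(proteomes, key=lambda r: r.protein_id)
    ]
    write_fasta(records, path)


def read_proteomes_fasta(path: PathLike):
    """Reference store from a FASTA with ``taxon=``/``function=`` header
    tags (``family=`` optional)."""
    from .simulate import ReferenceProteinRecord

    out = []
    for header, seq in read_fasta(path):
        fields = header.split(" ")
        pid = fields[0]
        tags = {}
        key = None
        for tok in fields[1:]:
            if "=" in tok:
                key, val = tok.split("=", 1)
                tags[key] = val
            elif key:  # function names contain spaces
                tags[key] += " " + tok
        if "taxon" not in tags:
            raise DataError(f"{path}: record {pid!r} lacks taxon= tag")
        out.append(ReferenceProteinRecord(
            protein_id=pid, sequence=seq, taxon_id=tags["taxon"],
            function_name=tags.get("function", ""),
            family_id=tags.get("family", pid)))
    return out
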