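"""Synthetic community, reference proteomes, reads, and observed peptidomes.

Everything is a pure function of (arguments, seed): a fixed seed reproduces
identical output byte for byte. Hidden ground truth (read sources, peptide
sources) is carried along so recovery tests can close the loop.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import digestion
from ._seq import AA_ALPHABET, NT_ALPHABET, reverse_translate, revcomp
from .taxonomy import TaxonomyTree

GEL_BASED = "gel_based"
GEL_FREE = "gel_free"
PEPTIDOME_LABELS = (GEL_BASED, GEL_FREE)

# pool of plausible base function names; families cycle through it
_FUNCTION_BASES = [
    "60 kDa chaperonin", "ATP synthase", "elongation factor Tu",
    "DNA-binding protein", "amino-acid ABC transporter-binding protein",
    "50S ribosomal protein", "30S ribosomal protein", "10 kDa chaperonin",
    "chaperone protein DnaK", "ribulose bisphosphate carboxylase",
    "photosystem II protein", "phycobilisome linker polypeptide",
    "TonB-dependent receptor", "glutamine synthetase", "superoxide dismutase",
    "ferredoxin", "malate dehydrogenase", "citrate synthase", "enolase",
    "phosphate-binding protein", "nitrogen regulatory protein",
    "peroxiredoxin", "thioredoxin", "porin", "flagellin",
    "outer membrane protein", "glyceraldehyde-3-phosphate dehydrogenase",
    "isocitrate dehydrogenase", "aconitate hydratase", "pyruvate kinase",
]
_DESIGNATOR_VARIANTS = ["", " subunit alpha", " subunit beta",
                        " subunit gamma", " 1", " 2"]


@dataclass(frozen=True)
class ReferenceProteinRecord:
    protein_id: str
    sequence: str
    taxon_id: str          # genus-level node
    function_name: str
    family_id: str


@dataclass(frozen=True)
class CommunityProfile:
    """Genus taxon_id -> relative abundance; abundances > 0 and sum to 1."""

    abundances: dict[str, float]

    def __post_init__(self):
        if not self.abundances:
            raise ValueError("empty community")
        if any(a <= 0 for a in self.abundances.values()):
            raise ValueError("abundances must be positive")
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, not 1")


@dataclass(frozen=True)
class ReadSource:
    protein_id: str
    strand: str            # '+' or '-'
    start: int             # 0-based half-open on the forward coding sequence
    end: int


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]
    source: Optional[ReadSource] = None

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError("read length must be >= 1")
        if len(self.qualities) != len(self.sequence):
            raise ValueError(f"quality/sequence length mismatch in {self.read_id}")
        if set(self.sequence) - set(NT_ALPHABET):
            raise ValueError(f"non-ACGT base in {self.read_id}")


@dataclass
class ReadSet:
    reads: list[Read] = field(default_factory=list)

    def __len__(self):
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


@dataclass
class ObservedPeptidome:
    """Stand-in for one MS dataset: peptide -> spectrum count, plus truth.

    ``truth`` maps every observed peptide to the frozenset of reference
    proteins whose tryptic digest contains it; noise peptides map to an
    empty set.
    """

    label: str
    observations: dict[str, int]
    truth: dict[str, frozenset[str]]

    def __post_init__(self):
        if self.label not in PEPTIDOME_LABELS:
            raise ValueError(f"label must be one of {PEPTIDOME_LABELS}")

    @property
    def total_spectra(self) -> int:
        return sum(self.observations.values())

    def is_noise(self, peptide: str) -> bool:
        return not self.truth.get(peptide, frozenset())


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_reference_proteomes(
    tree: TaxonomyTree,
    n_proteins_per_genus: int,
    n_families: int,
    within_family_identity: float = 0.9,
    seed: int = 0,
    min_length: int = 120,
    max_length: int = 300,
) -> list[ReferenceProteinRecord]:
    """Reference store: ``n_proteins_per_genus`` records per genus, grouped
    into homolog families that span >= 2 genera (when families are fewer
    than proteins), each family derived from one ancestral sequence by
    point substitutions at rate ``1 - within_family_identity``."""
    if not 0.5 <= within_family_identity <= 1.0:
        raise ValueError("within_family_identity must be in [0.5, 1.0]")
    if n_proteins_per_genus < 1:
        raise ValueError("n_proteins_per_genus must be >= 1")
    rng = np.random.default_rng(seed)
    genera = tree.genus_ids
    # protein-index-major slot order interleaves genera so a family's
    # members land in different genera
    slots = [(g, i) for i in range(n_proteins_per_genus) for g in genera]
    total = len(slots)
    n_families = min(max(n_families, 0), total)

    if n_families == 0:
        family_of = list(range(total))     # every protein a singleton family
        n_anc = total
    else:
        # block-shifted round-robin: within each block of n_families slots
        # the assignment is rotated by the block index, so a family's
        # members land in different genera across blocks
        family_of = [(s + s // n_families) % n_families for s in range(total)]
        n_anc = n_families
        if len(genera) >= 2:
            _fix_single_genus_families(slots, family_of)

    aa = np.array(list(AA_ALPHABET))
    ancestors = []
    fam_bases = []
    for f in range(n_anc):
        length = int(rng.integers(min_length, max_length + 1))
        ancestors.append("".join(rng.choice(aa, size=length)))
        base = _FUNCTION_BASES[f % len(_FUNCTION_BASES)]
        if f >= len(_FUNCTION_BASES):
            base = f"{base} type {f // len(_FUNCTION_BASES) + 1}"
        fam_bases.append(base)

    mut_rate = 1.0 - within_family_identity
    records = []
    per_genus_counter: dict[str, int] = {g: 0 for g in genera}
    for (genus, _idx), fam in zip(slots, family_of):
        anc = ancestors[fam]
        seq = _mutate(anc, mut_rate, rng, aa)
        designator = _DESIGNATOR_VARIANTS[
            int(rng.integers(0, len(_DESIGNATOR_VARIANTS)))
        ]
        per_genus_counter[genus] += 1
        records.append(
            ReferenceProteinRecord(
                protein_id=f"{genus}_p{per_genus_counter[genus]:04d}",
                sequence=seq,
                taxon_id=genus,
                function_name=fam_bases[fam] + designator,
                family_id=f"fam{fam:05d}",
            )
        )
    return records


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            aa: np.ndarray) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hits):
        choices = [c for c in AA_ALPHABET if c != arr[i]]
        arr[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(arr)


def _fix_single_genus_families(slots, family_of):
    """Swap slot assignments so every multi-member family spans >= 2
    genera. Swaps are only applied when they provably fix the bad family
    without collapsing the donor family to one genus; repeated passes run
    until stable."""

    def genera_of(members: list[int], minus: int = -1, plus: int = -1):
        gs = {slots[i][0] for i in members if i != minus}
        if plus >= 0:
            gs.add(slots[plus][0])
        return gs

    for _ in range(len(set(family_of)) + 1):
        members: dict[int, list[int]] = {}
        for idx, fam in enumerate(family_of):
            members.setdefault(fam, []).append(idx)
        bad = [
            fam for fam, idxs in sorted(members.items())
            if len(idxs) >= 2 and len(genera_of(idxs)) == 1
        ]
        if not bad:
            return
        progressed = False
        for fam in bad:
            idxs = members[fam]
            victim = idxs[0]
            lone = slots[victim][0]
            for j in range(len(slots)):
                other = family_of[j]
                if slots[j][0] == lone or other == fam:
                    continue
                donor = members[other]
                # donor must stay multi-genus (or be a singleton family)
                if len(donor) >= 2 and \
                        len(genera_of(donor, minus=j, plus=victim)) < 2:
                    continue
                family_of[j], family_of[victim] = fam, other
                members[other] = [i for i in donor if i != j] + [victim]
                members[fam] = [i for i in idxs if i != victim] + [j]
                progressed = True
                break
        if not progressed:
            break


def simulate_community(
    tree: TaxonomyTree, n_present: int, skew: float = 1.0, seed: int = 0
) -> CommunityProfile:
    """Pick ``n_present`` genera and give them normalized log-normal(0, skew)
    abundances."""
    genera = tree.genus_ids
    if not 1 <= n_present <= len(genera):
        raise ValueError(
            f"n_present must be in [1, {len(genera)}], got {n_present}")
    if skew < 0:
        raise ValueError("skew must be >= 0")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(genera, size=n_present, replace=False))
    draws = np.exp(rng.normal(0.0, skew, size=n_present))
    draws /= draws.sum()
    return CommunityProfile(dict(zip(chosen, draws.tolist())))


def simulate_reads(
    community: CommunityProfile,
    proteomes: list[ReferenceProteinRecord],
    read_length: int = 150,
    n_reads: int = 2000,
    error_rate: float = 0.005,
    seed: int = 0,
    base_quality: int = 38,
    tail_quality: int = 2,
    low_quality_tail_fraction: float = 0.1,
) -> ReadSet:
    """Short reads off the fixed-codon coding sequences of proteins drawn
    proportionally to genus abundance.

    Strand is uniform; substitution errors are applied at ``error_rate``;
    with probability ``low_quality_tail_fraction`` a read gets a low-quality
    3' tail (so quality trimming has something to do). The true source
    (protein, strand, forward-CDS coordinates) is recorded per read.
    """
    if read_length < 30:
        raise ValueError("read_length must be >= 30")
    if not 0 <= error_rate < 0.2:
        raise ValueError("error_rate must be in [0, 0.2)")
    if not community.abundances:
        raise ValueError("empty community")
    rng = np.random.default_rng(seed)

    by_genus: dict[str, list[ReferenceProteinRecord]] = {}
    for rec in proteomes:
        by_genus.setdefault(rec.taxon_id, []).append(rec)
    pool: list[tuple[ReferenceProteinRecord, float]] = []
    for genus, ab in sorted(community.abundances.items()):
        recs = [r for r in by_genus.get(genus, [])
                if len(r.sequence) * 3 + 3 >= read_length]
        for r in sorted(recs, key=lambda r: r.protein_id):
            pool.append((r, ab / len(recs)))
    if not pool:
        raise ValueError("no community protein long enough for read_length")

    cds_cache = {r.protein_id: reverse_translate(r.sequence) for r, _ in pool}
    weights = np.array([w for _, w in pool])
    weights /= weights.sum()

    reads = []
    picks = rng.choice(len(pool), size=n_reads, p=weights)
    for i, pick in enumerate(picks):
        rec = pool[int(pick)][0]
        cds = cds_cache[rec.protein_id]
        start = int(rng.integers(0, len(cds) - read_length + 1))
        end = start + read_length
        seq = cds[start:end]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        if error_rate > 0:
            arr = np.array(list(seq))
            hits = rng.random(read_length) < error_rate
            for p in np.flatnonzero(hits):
                alts = [c for c in NT_ALPHABET if c != arr[p]]
                arr[p] = alts[int(rng.integers(0, 3))]
            seq = "".join(arr)
        quals = [base_quality] * read_length
        if rng.random() < low_quality_tail_fraction:
            tail = int(rng.integers(5, max(6, read_length // 3)))
            for p in range(read_length - tail, read_length):
                quals[p] = tail_quality
        reads.append(
            Read(
                read_id=f"read{i:06d}",
                sequence=seq,
                qualities=tuple(quals),
                source=ReadSource(rec.protein_id, strand, start, end),
            )
        )
    return ReadSet(reads)


def build_peptide_truth_index(
    proteomes: list[ReferenceProteinRecord],
    max_missed_cleavages: int = 2,
    min_len: int = 6,
    max_len: int = 40,
) -> dict[str, frozenset[str]]:
    """Peptide -> all reference proteins whose digest contains it."""
    index: dict[str, set[str]] = {}
    for rec in proteomes:
        for pep in digestion.digest(rec.sequence, max_missed_cleavages,
                                    min_len, max_len):
            index.setdefault(pep, set()).add(rec.protein_id)
    return {p: frozenset(s) for p, s in index.items()}


def simulate_peptidome(
    community: CommunityProfile,
    proteomes: list[ReferenceProteinRecord],
    label: str,
    n_spectra: int,
    max_missed_cleavages: int = 2,
    noise_fraction: float = 0.05,
    detectability_bias: float = 0.0,
    seed: int = 0,
    min_len: int = 6,
    max_len: int = 40,
) -> ObservedPeptidome:
    """Spectra as draws of tryptic peptides from proteins drawn
    proportionally to genus abundance x per-protein log-normal(0,1)
    expression weight; ``noise_fraction`` of spectra are random tryptic-like
    peptides absent from every proteome.

    ``detectability_bias`` > 0 sharpens the sampling weights
    (w -> w**(1+bias)), the stand-in for gel-based fractionation favouring
    abundant proteins.
    """
    if label not in PEPTIDOME_LABELS:
        raise ValueError(f"label must be one of {PEPTIDOME_LABELS}")
    if not 0 <= noise_fraction < 0.5:
        raise ValueError("noise_fraction must be in [0, 0.5)")
    if n_spectra < 0:
        raise ValueError("n_spectra must be >= 0")
    rng = np.random.default_rng(seed)

    truth_index = build_peptide_truth_index(
        proteomes, max_missed_cleavages, min_len, max_len)

    by_genus: dict[str, list[ReferenceProteinRecord]] = {}
    for rec in proteomes:
        by_genus.setdefault(rec.taxon_id, []).append(rec)
    pool = []
    weights = []
    digests = []
    for genus, ab in sorted(community.abundances.items()):
        recs = sorted(by_genus.get(genus, []), key=lambda r: r.protein_id)
        for rec in recs:
            peps = sorted(digestion.digest(rec.sequence, max_missed_cleavages,
                                           min_len, max_len))
            if not peps:
                continue
            expr = math.exp(rng.normal(0.0, 1.0))
            pool.append(rec)
            digests.append(peps)
            weights.append((ab / len(recs)) * expr)
    if not pool and n_spectra > 0 and noise_fraction < 1:
        raise ValueError("no digestible community protein")

    w = np.array(weights, dtype=float)
    if detectability_bias > 0:
        w = w ** (1.0 + detectability_bias)
    w /= w.sum()

    n_noise = int(round(n_spectra * noise_fraction))
    n_signal = n_spectra - n_noise

    observations: dict[str, int] = {}
    truth: dict[str, frozenset[str]] = {}

    picks = rng.choice(len(pool), size=n_signal, p=w)
    for pick in picks:
        peps = digests[int(pick)]
        pep = peps[int(rng.integers(0, len(peps)))]
        observations[pep] = observations.get(pep, 0) + 1
        truth[pep] = truth_index[pep]

    aa_body = list(AA_ALPHABET)
    for _ in range(n_noise):
        while True:
            length = int(rng.integers(8, 21))
            body = "".join(
                aa_body[int(k)] for k in rng.integers(0, 20, size=length - 1))
            pep = body + ("K" if rng.random() < 0.5 else "R")
            if pep not in truth_index:
                break
        observations[pep] = observations.get(pep, 0) + 1
        truth[pep] = frozenset()

    return ObservedPeptidome(label=label, observations=observations,
                             truth=truth)
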