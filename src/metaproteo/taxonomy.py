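"""Rooted taxonomy with the fixed rank ladder domain -> genus.

The tree is the backbone for lowest-common-ancestor (LCA) consensus
annotation and for rolling identifications up to an arbitrary rank.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}


@dataclass(frozen=True)
class TaxNode:
    taxon_id: str
    name: str
    rank: str
    parent_id: Optional[str]  # None only for the root


class TaxonomyTree:
    """Immutable rooted tree of :class:`TaxNode` keyed by ``taxon_id``."""

    def __init__(self, nodes: Iterable[TaxNode]):
        self.nodes: dict[str, TaxNode] = {}
        for n in nodes:
            if n.taxon_id in self.nodes:
                raise ValueError(f"duplicate taxon_id {n.taxon_id!r}")
            if n.rank not in RANK_DEPTH:
                raise ValueError(f"unknown rank {n.rank!r} for {n.taxon_id!r}")
            self.nodes[n.taxon_id] = n
        self._children: dict[str, list[str]] = {tid: [] for tid in self.nodes}
        roots = []
        for n in self.nodes.values():
            if n.parent_id is None:
                roots.append(n.taxon_id)
            else:
                if n.parent_id not in self.nodes:
                    raise ValueError(
                        f"taxon {n.taxon_id!r} has unknown parent {n.parent_id!r}"
                    )
                parent = self.nodes[n.parent_id]
                if RANK_DEPTH[n.rank] <= RANK_DEPTH[parent.rank]:
                    raise ValueError(
                        f"rank of {n.taxon_id!r} ({n.rank}) is not below its "
                        f"parent's ({parent.rank})"
                    )
                self._children[n.parent_id].append(n.taxon_id)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.root_id = roots[0]
        for kids in self._children.values():
            kids.sort()

    # -- queries ---------------------------------------------------------
    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, taxon_id: str) -> TaxNode:
        try:
            return self.nodes[taxon_id]
        except KeyError:
            raise KeyError(f"unknown taxon {taxon_id!r}") from None

    def children_of(self, taxon_id: str) -> list[str]:
        return list(self._children[taxon_id])

    def path_to_root(self, taxon_id: str) -> list[str]:
        """Taxon ids from ``taxon_id`` up to and including the root."""
        path = []
        cur: Optional[str] = taxon_id
        while cur is not None:
            path.append(cur)
            cur = self.node(cur).parent_id
        return path

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> Optional[TaxNode]:
        """Ancestor-or-self of ``taxon_id`` at ``rank``, or None if the
        node is shallower than ``rank``."""
        if rank not in RANK_DEPTH:
            raise ValueError(f"unknown rank {rank!r}")
        for tid in self.path_to_root(taxon_id):
            if self.node(tid).rank == rank:
                return self.node(tid)
        return None

    @property
    def genus_ids(self) -> list[str]:
        return sorted(t for t, n in self.nodes.items() if n.rank == "genus")

    def lca(self, taxon_ids: Iterable[str]) -> Optional[TaxNode]:
        """Deepest node that is ancestor-or-self of every input taxon.

        Returns None for an empty input.
        """
        ids = list(taxon_ids)
        if not ids:
            return None
        common = set(self.path_to_root(ids[0]))
        for tid in ids[1:]:
            common &= set(self.path_to_root(tid))
        # the path of any member through `common` is a chain; deepest wins
        deepest = max(common, key=lambda t: RANK_DEPTH[self.node(t).rank])
        return self.node(deepest)


_RANK_PREFIX = {"domain": "d", "phylum": "p", "class": "c",
                "order": "o", "family": "f", "genus": "g"}


def generate_taxonomy(n_genera: int, branching: Optional[tuple[int, ...]] = None,
                      seed: int = 0) -> TaxonomyTree:
    """Deterministically build a taxonomy with exactly ``n_genera`` genus
    leaves.

    ``branching`` gives per-rank branching factors for the five ranks below
    domain; when omitted, the smallest uniform factor whose product covers
    ``n_genera`` is used and surplus genus leaves are pruned (breadth-first
    order). ``seed`` is accepted for API uniformity; construction is fully
    deterministic.
    """
    del seed  # deterministic by construction
    if n_genera < 1:
        raise ValueError("n_genera must be >= 1")
    if branching is None:
        b = 1
        while b ** 5 < n_genera:
            b += 1
        branching = (b,) * 5
    branching = tuple(int(x) for x in branching)
    if len(branching) != 5:
        raise ValueError("branching must give 5 factors (phylum..genus)")
    if any(x < 1 for x in branching):
        raise ValueError("branching factors must be >= 1")
    prod = 1
    for x in branching:
        prod *= x
    if prod < n_genera:
        raise ValueError(
            f"branching product {prod} cannot host {n_genera} genera")

    counters = {r: 0 for r in RANKS}
    nodes: list[TaxNode] = []

    def new_node(rank: str, parent: Optional[str]) -> TaxNode:
        counters[rank] += 1
        tid = f"{_RANK_PREFIX[rank]}{counters[rank]:03d}"
        node = TaxNode(tid, f"{rank.capitalize()}_{counters[rank]:03d}",
                       rank, parent)
        nodes.append(node)
        return node

    level = [new_node("domain", None)]
    for rank, factor in zip(RANKS[1:], branching):
        nxt = []
        for parent in level:
            for _ in range(factor):
                nxt.append(new_node(rank, parent.taxon_id))
        level = nxt
    # prune surplus genus leaves (keep first n_genera in BFS order), then
    # drop ancestors left without a genus descendant
    keep_genus = {n.taxon_id for n in level[:n_genera]}
    kept: set[str] = set()
    by_id = {n.taxon_id: n for n in nodes}
    for gid in keep_genus:
        cur: Optional[str] = gid
        while cur is not None and cur not in kept:
            kept.add(cur)
            cur = by_id[cur].parent_id
    return TaxonomyTree([n for n in nodes if n.taxon_id in kept])
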