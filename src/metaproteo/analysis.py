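"""Comparative analytics across metaproteomes.

Distribution tables with <1% pooling into "Other", annotation-rate
profiles, four-set Venn partitions, mean +/- SEM row summaries, and
complete-linkage clustered taxon x function matrices.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import spearmanr

from .annotate import AnnotatedMetaproteome, annotation_fractions
from .simulate import CommunityProfile, ObservedPeptidome, ReferenceProteinRecord
from .taxonomy import RANK_DEPTH, RANKS, TaxonomyTree

OTHER_LABEL = "Other"


@dataclass
class DistributionTable:
    axis: str                      # "taxon@<rank>" or "function"
    weighting: str                 # "peptide_count" | "protein_count"
    other_threshold: float         # percent
    rows: dict[str, float]         # label -> proportion percent

    @property
    def total(self) -> float:
        return sum(self.rows.values())


def _pool_other(proportions: dict[str, float], threshold: float) -> dict[str, float]:
    kept = {k: v for k, v in proportions.items() if v >= threshold}
    other = sum(v for k, v in proportions.items() if v < threshold)
    out = dict(sorted(kept.items(), key=lambda kv: (-kv[1], kv[0])))
    if other > 0:
        out[OTHER_LABEL] = other
    return out


def _group_weight(group, weighting: str) -> float:
    if weighting == "peptide_count":
        return float(group.n_distinct_peptides)
    if weighting == "protein_count":
        return 1.0
    raise ValueError(f"unknown weighting {weighting!r}")


def taxon_distribution(
    am: AnnotatedMetaproteome,
    tree: TaxonomyTree,
    rank: str,
    weighting: str = "peptide_count",
    other_threshold: float = 1.0,
) -> DistributionTable:
    """Proportions (percent) of groups rolled up to their ``rank``-level
    ancestor, weighted by distinct peptides per group (or 1 in
    protein_count mode); labels under ``other_threshold`` percent pool
    into "Other"."""
    if rank not in RANK_DEPTH:
        raise ValueError(f"invalid rank {rank!r}")
    weights: dict[str, float] = {}
    for group in am.result.groups:
        tax = am.taxonomic.get(group.group_id)
        if tax is None or tax.rank is None:
            continue
        if RANK_DEPTH[tax.rank] < RANK_DEPTH[rank]:
            continue
        node = tree.ancestor_at_rank(tax.taxon_id, rank)
        if node is None:
            continue
        weights[node.name] = weights.get(node.name, 0.0) + _group_weight(
            group, weighting)
    total = sum(weights.values())
    props = {k: 100.0 * v / total for k, v in weights.items()} if total else {}
    return DistributionTable(
        axis=f"taxon@{rank}", weighting=weighting,
        other_threshold=other_threshold,
        rows=_pool_other(props, other_threshold))


def function_distribution(
    am: AnnotatedMetaproteome,
    weighting: str = "peptide_count",
    other_threshold: float = 1.0,
) -> DistributionTable:
    """As :func:`taxon_distribution` but keyed by consensus function name;
    unnamed / needs-manual groups are excluded from the denominator."""
    weights: dict[str, float] = {}
    for group in am.result.groups:
        func = am.functional.get(group.group_id)
        if func is None or func.name is None:
            continue
        weights[func.name] = weights.get(func.name, 0.0) + _group_weight(
            group, weighting)
    total = sum(weights.values())
    props = {k: 100.0 * v / total for k, v in weights.items()} if total else {}
    return DistributionTable(
        axis="function", weighting=weighting,
        other_threshold=other_threshold,
        rows=_pool_other(props, other_threshold))


def annotation_rate_profile(
    ams: dict[str, AnnotatedMetaproteome]) -> pd.DataFrame:
    """Rows = ranks (domain..genus), columns = metaproteome ids, values =
    fraction of accepted groups annotated at that rank or deeper."""
    data = {mid: annotation_fractions(am) for mid, am in ams.items()}
    return pd.DataFrame(data, index=list(RANKS))


def venn_partition(sets_by_name: dict[str, set]) -> dict[frozenset, int]:
    """Counts for the 15 non-empty membership regions of exactly 4 sets."""
    if len(sets_by_name) != 4:
        raise ValueError("venn_partition requires exactly 4 sets")
    names = sorted(sets_by_name)
    universe = set().union(*sets_by_name.values())
    regions: dict[frozenset, int] = {}
    for item in universe:
        key = frozenset(n for n in names if item in sets_by_name[n])
        regions[key] = regions.get(key, 0) + 1
    # ensure all 15 regions are present
    from itertools import combinations
    for r in range(1, 5):
        for combo in combinations(names, r):
            regions.setdefault(frozenset(combo), 0)
    return regions


def round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def round_sem(sem: float) -> float:
    """Display rounding for SEM: one decimal at >= 1, two below."""
    return round_half_up(sem, 1 if sem >= 1 else 2)


def summarize_mean_sem(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row arithmetic mean and standard error of the mean (sample SD
    with n-1 divisor over sqrt(n)) across columns."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    mean = matrix.mean(axis=1)
    sem = matrix.std(axis=1, ddof=1) / np.sqrt(matrix.shape[1])
    return pd.DataFrame({"mean": mean, "sem": sem})


def taxon_function_matrix(
    am: AnnotatedMetaproteome, tree: TaxonomyTree, rank: str = "order"
) -> pd.DataFrame:
    """Rows = ``rank``-level taxa, columns = consensus functions, cells =
    summed distinct-peptide counts of groups carrying both annotations."""
    cells: dict[tuple[str, str], float] = {}
    for group in am.result.groups:
        tax = am.taxonomic.get(group.group_id)
        func = am.functional.get(group.group_id)
        if tax is None or tax.rank is None or func is None or func.name is None:
            continue
        if RANK_DEPTH[tax.rank] < RANK_DEPTH[rank]:
            continue
        node = tree.ancestor_at_rank(tax.taxon_id, rank)
        if node is None:
            continue
        key = (node.name, func.name)
        cells[key] = cells.get(key, 0.0) + group.n_distinct_peptides
    if not cells:
        return pd.DataFrame()
    rows = sorted({k[0] for k in cells})
    cols = sorted({k[1] for k in cells})
    mat = pd.DataFrame(0.0, index=rows, columns=cols)
    for (r, c), v in cells.items():
        mat.loc[r, c] = v
    return mat


def cluster_heatmap(matrix: pd.DataFrame):
    """Complete-linkage hierarchical clustering (Euclidean metric) of rows
    and columns independently.

    Returns (row_linkage, col_linkage, ordered_matrix); linkages are scipy
    4-column merge tables, ordering follows dendrogram leaf order.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least a 2x2 matrix")
    row_link = linkage(matrix.values, method="complete", metric="euclidean")
    col_link = linkage(matrix.values.T, method="complete", metric="euclidean")
    row_order = leaves_list(row_link)
    col_order = leaves_list(col_link)
    ordered = matrix.iloc[row_order, col_order]
    return row_link, col_link, ordered


def ground_truth_report(
    am: AnnotatedMetaproteome,
    tree: TaxonomyTree,
    community: CommunityProfile,
    proteomes: list[ReferenceProteinRecord],
    peptidome: ObservedPeptidome,
    min_distinct_peptides: int = 2,
) -> dict:
    """Recovery metrics against the hidden simulation truth.

    * genus_spearman: Spearman correlation between the genus-level
      peptide-weighted distribution and the true abundances (None when
      undefined).
    * protein_recovery: fraction of truly observed proteins (>=
      ``min_distinct_peptides`` sampled distinct peptides) present as a
      member of an accepted group (matched by entry id, else by sharing a
      sampled peptide with an accepted group).
    * function_recovery: fraction of named groups whose consensus function
      matches the normalized true function of a truth protein of one of
      its peptides.
    """
    from .annotate import normalize_function_name

    # --- genus-level correlation -------------------------------------
    observed: dict[str, float] = {}
    for group in am.result.groups:
        tax = am.taxonomic.get(group.group_id)
        if tax is None or tax.rank is None:
            continue
        node = tree.ancestor_at_rank(tax.taxon_id, "genus")
        if node is None:
            continue
        observed[node.taxon_id] = observed.get(node.taxon_id, 0.0) + \
            group.n_distinct_peptides
    genera = sorted(community.abundances)
    spearman = None
    if observed and len(genera) >= 2:
        obs_vec = [observed.get(g, 0.0) for g in genera]
        true_vec = [community.abundances[g] for g in genera]
        if len(set(obs_vec)) > 1:
            rho, _ = spearmanr(obs_vec, true_vec)
            spearman = float(rho)

    # --- protein recovery --------------------------------------------
    sampled_peps: dict[str, set[str]] = {}
    for pep, sources in peptidome.truth.items():
        for pid in sources:
            sampled_peps.setdefault(pid, set()).add(pep)
    candidates = {p for p, peps in sampled_peps.items()
                  if len(peps) >= min_distinct_peptides}
    member_ids = {m for g in am.result.groups for m in g.member_entry_ids}
    accepted_peps = {p for g in am.result.groups for p in g.peptides}
    recovered = {
        p for p in candidates
        if p in member_ids or sampled_peps[p] & accepted_peps
    }
    protein_recovery = (len(recovered) / len(candidates)) if candidates else None

    # --- function recovery -------------------------------------------
    func_of = {rec.protein_id: normalize_function_name(rec.function_name)
               for rec in proteomes}
    named = 0
    matched = 0
    for group in am.result.groups:
        func = am.functional.get(group.group_id)
        if func is None or func.name is None:
            continue
        named += 1
        true_funcs = {
            func_of[pid]
            for pep in group.peptides
            for pid in peptidome.truth.get(pep, frozenset())
            if pid in func_of
        }
        if func.name in true_funcs:
            matched += 1
    function_recovery = (matched / named) if named else None

    return {
        "genus_spearman": spearman,
        "protein_recovery": protein_recovery,
        "function_recovery": function_recovery,
        "n_candidate_proteins": len(candidates),
        "n_accepted_groups": len(am.result.groups),
    }
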