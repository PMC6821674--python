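"""End-to-end orchestration: simulate -> build databases -> two-round
searches -> annotate -> analytics, with a manifest for reproducibility."""
from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import asdict
from pathlib import Path

from . import analysis, annotate, dbbuild, io, search, simulate, taxonomy
from .config import ExperimentConfig, stage_seed
from .search import DigestParams

DB_ORDER = ("NAM", "AM", "TAX", "Comb")


def simulate_inputs(cfg: ExperimentConfig):
    """Taxonomy, proteomes, community, reads, and both peptidomes."""
    tree = taxonomy.generate_taxonomy(cfg.n_genera,
                                      seed=stage_seed(cfg.seed, "taxonomy"))
    proteomes = simulate.generate_reference_proteomes(
        tree, cfg.n_proteins_per_genus, cfg.n_families,
        cfg.within_family_identity, seed=stage_seed(cfg.seed, "proteomes"))
    community = simulate.simulate_community(
        tree, cfg.n_present, cfg.community_skew,
        seed=stage_seed(cfg.seed, "community"))
    reads = simulate.simulate_reads(
        community, proteomes, cfg.read_length, cfg.n_reads, cfg.error_rate,
        seed=stage_seed(cfg.seed, "reads"))
    pep_seed = cfg.peptidome_seed if cfg.peptidome_seed is not None else cfg.seed
    peptidomes = {
        simulate.GEL_FREE: simulate.simulate_peptidome(
            community, proteomes, simulate.GEL_FREE, cfg.gel_free_spectra,
            cfg.max_missed_cleavages, cfg.noise_fraction, 0.0,
            seed=stage_seed(pep_seed, "peptidome_gel_free"),
            min_len=cfg.min_peptide_len, max_len=cfg.max_peptide_len),
        simulate.GEL_BASED: simulate.simulate_peptidome(
            community, proteomes, simulate.GEL_BASED, cfg.gel_based_spectra,
            cfg.max_missed_cleavages, cfg.noise_fraction,
            cfg.detectability_bias,
            seed=stage_seed(pep_seed, "peptidome_gel_based"),
            min_len=cfg.min_peptide_len, max_len=cfg.max_peptide_len),
    }
    return tree, proteomes, community, reads, peptidomes


def build_databases(cfg: ExperimentConfig, reads, proteomes):
    """Trimmed reads -> NAM, AM, TAX round-1 databases."""
    trimmed = dbbuild.trim_reads(reads, cfg.min_mean_quality,
                                 cfg.min_read_length)
    nam = dbbuild.build_nam_db(trimmed, cfg.min_orf_aa)
    am = dbbuild.build_am_db(trimmed, cfg.min_overlap, cfg.min_orf_aa,
                             cfg.drop_singletons)
    markers = dbbuild.build_marker_index(proteomes)
    detected = dbbuild.detect_taxa(trimmed, markers, cfg.marker_min_hits)
    tax = dbbuild.build_taxonomy_db(detected, proteomes)
    return trimmed, {"NAM": nam, "AM": am, "TAX": tax}, detected


def run_experiment(cfg: ExperimentConfig, out_dir, resume: bool = False):
    """One command for the whole eight-metaproteome experiment.

    Writes all artifacts (FASTA/FASTQ/TSV + manifest.json) under
    ``out_dir`` and returns a dict with the in-memory objects. Without
    ``resume`` any existing output directory content is cleaned first.
    """
    cfg.validate()
    out = Path(out_dir)
    if out.exists() and not resume:
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)

    params = DigestParams(cfg.max_missed_cleavages, cfg.min_peptide_len,
                          cfg.max_peptide_len)

    # --- stage 1: simulation -----------------------------------------
    tree, proteomes, community, reads, peptidomes = simulate_inputs(cfg)
    io.write_taxonomy(tree, out / "taxonomy.tsv", out / "taxonomy_names.tsv")
    io.write_proteomes_fasta(proteomes, out / "reference_proteomes.fasta")
    with open(out / "community.tsv", "w") as fh:
        fh.write("taxon_id\tabundance\n")
        for g in sorted(community.abundances):
            fh.write(f"{g}\t{community.abundances[g]:.10f}\n")
    io.write_fastq(reads, out / "reads.fastq")
    for label, pep in peptidomes.items():
        io.write_peptidome(pep, out / f"peptidome_{label}.tsv",
                           out / f"peptidome_{label}_truth.tsv")

    # --- stage 2: databases ------------------------------------------
    trimmed, dbs, detected = build_databases(cfg, reads, proteomes)
    with open(out / "detected_taxa.tsv", "w") as fh:
        fh.write("taxon_id\n")
        for g in sorted(detected):
            fh.write(g + "\n")
    for name, db in dbs.items():
        io.write_protein_db(db, out / f"db_{name}_round1.fasta")

    # --- stage 3: searches -------------------------------------------
    results, comb_dbs, summary, restricted_dbs = search.run_workflow(
        peptidomes, dbs, params, cfg.fdr, with_restricted=True)
    for label, comb in comb_dbs.items():
        io.write_protein_db(comb, out / f"db_Comb_{label}.fasta")
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    for (label, db_name, rnd), res in results.items():
        io.write_search_result(
            res, out / f"result_{label}_{db_name}_round{rnd}.tsv")

    # --- stage 4: annotation -----------------------------------------
    # second-round (final) metaproteomes only: the eight comparative units
    searchable = dict(restricted_dbs)
    for label in peptidomes:
        searchable[(label, "Comb")] = comb_dbs[label]

    cache: dict = {}
    ams: dict[str, annotate.AnnotatedMetaproteome] = {}
    for label in sorted(peptidomes):
        for db_name in DB_ORDER:
            res = results[(label, db_name, 2)]
            db = searchable[(label, db_name)]
            anchors = annotate.anchor_sequence_map(res, db)
            am = annotate.annotate_all(
                res, anchors, proteomes, tree, cfg.max_hits,
                cfg.min_bitscore, cfg.consensus_tolerance,
                prefilter=True, prefilter_top=cfg.prefilter_top,
                cache=cache)
            mid = f"{label}/{db_name}"
            ams[mid] = am
            io.write_annotations(am, out / f"annotations_{label}_{db_name}.tsv")

    # --- stage 5: analytics ------------------------------------------
    rates = analysis.annotation_rate_profile(ams)
    rates.to_csv(out / "annotation_rates.tsv", sep="\t")
    for mid, am in ams.items():
        tag = mid.replace("/", "_")
        io.write_distribution(
            analysis.taxon_distribution(am, tree, "order",
                                        other_threshold=cfg.other_threshold),
            out / f"taxon_distribution_order_{tag}.tsv")
        io.write_distribution(
            analysis.function_distribution(
                am, other_threshold=cfg.other_threshold),
            out / f"function_distribution_{tag}.tsv")

    for label in sorted(peptidomes):
        order_sets = {
            db: {
                lbl for lbl in analysis.taxon_distribution(
                    ams[f"{label}/{db}"], tree, "order",
                    other_threshold=0.0).rows
            }
            for db in DB_ORDER
        }
        venn = analysis.venn_partition(order_sets)
        with open(out / f"venn_orders_{label}.tsv", "w") as fh:
            fh.write("region\tcount\n")
            for key in sorted(venn, key=lambda k: (len(k), sorted(k))):
                fh.write("+".join(sorted(key)) + f"\t{venn[key]}\n")

    manifest = _write_manifest(cfg, out)
    return {
        "tree": tree, "proteomes": proteomes, "community": community,
        "reads": reads, "trimmed_reads": trimmed, "peptidomes": peptidomes,
        "dbs": dbs, "comb_dbs": comb_dbs, "results": results,
        "summary": summary, "annotated": ams, "manifest": manifest,
    }


def _write_manifest(cfg: ExperimentConfig, out: Path) -> dict:
    checksums = {}
    for path in sorted(out.glob("*")):
        if path.name == "manifest.json" or path.is_dir():
            continue
        checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.content_hash(),
        "config": asdict(cfg),
        "checksums": checksums,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
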