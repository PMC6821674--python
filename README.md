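# metaproteo

Desk-scale comparative metaproteomics: build four protein search databases
from one synthetic metagenome, identify proteins with a two-round
target–decoy search at 1% protein-level FDR, annotate protein groups by
taxonomic lowest common ancestor (LCA) and consensus function, and compare
the resulting eight metaproteomes.

## What it does

- **`metaproteo.simulate`** — synthetic inputs with hidden ground truth: a
  multi-genus community with log-normal abundance skew, reference
  proteomes organized into homolog families, metagenomic short reads off
  fixed-codon coding sequences (both strands, substitution errors, quality
  tails), and two observed peptidomes (shallow "gel-based", deep
  "gel-free") as tryptic-peptide spectrum counts with noise peptides.
- **`metaproteo.dbbuild`** — the four databases from the same reads:
  - **NAM**: six-frame stop-free ORFs called directly on reads;
  - **AM**: greedy exact-overlap assembly into contigs, then the same ORF
    calling (singleton contigs dropped by default, which is what makes
    assembly lossy);
  - **TAX**: genera detected by marker k-mer counting, then the full
    reference proteome of every detected genus;
  - **Comb**: the merged, deduplicated union of the three second-round
    databases with freshly built decoys.
- **`metaproteo.search`** — peptide-centric stand-in for a spectrum search
  engine: exact matching against the tryptic peptide index, protein-group
  inference (identical peptide sets merge, nested sets are absorbed),
  pseudo-reversed decoys, FDR filtering (decoys/targets estimator) and a
  single-peptide validation rule, plus the two-round restricted search and
  the full eight-metaproteome workflow with a summary table.
- **`metaproteo.annotate`** — Smith–Waterman (BLOSUM62, gap 11/1) against
  the annotated reference store; up to 20 hits above bit score 80 drive
  the LCA and the modal-name consensus (accepted above 80% agreement,
  flagged for manual review otherwise).
- **`metaproteo.analysis`** — distribution tables with <1% pooling into
  "Other", annotation-rate profiles, 4-set Venn partitions, mean ± SEM
  summaries, taxon×function matrices with complete-linkage/Euclidean
  clustering, and ground-truth recovery metrics.
- **`metaproteo.workflow` / `metaproteo.cli`** — one-command orchestration
  with per-stage seed fan-out, TSV/FASTA/FASTQ artifacts and a manifest of
  checksums; reruns with the same config are bit-identical.

## CLI

```bash
metaproteo-compare run-all --seed 1 --out runs/demo          # everything
metaproteo-compare sim taxonomy --n-genera 8 --seed 1 --out tax.tsv
metaproteo-compare builddb nam --reads reads.fastq --out nam.fasta
metaproteo-compare builddb comb --inputs a.fasta --inputs b.fasta --out comb.fasta
metaproteo-compare search --peptidome pep.tsv --db nam.fasta --fdr 0.01 \
    --out result.tsv
metaproteo-compare annotate --result result.tsv --db nam.fasta \
    --refdb ref.fasta --taxonomy tax.tsv --names tax_names.tsv \
    --peptidome pep.tsv --out annotations.tsv
```

Exit codes: 0 ok, 2 configuration error, 3 data error. Configuration is a
YAML file mirroring `metaproteo.config.ExperimentConfig`; defaults follow
the published thresholds (1% protein FDR, 20 hits, bit score > 80,
consensus tolerance > 80%, "Other" pooling < 1%).

## Notes

- The search engine scores by spectrum counts and matches peptides
  exactly; there is no fragment-spectrum or mass-tolerance model.
- The alignment bit score uses the gapped Karlin–Altschul constants
  λ = 0.267, K = 0.041; "gap open 11, extend 1" means a gap of length L
  costs 11 + L.
- `--no-prefilter` style exhaustive alignment (the test oracle) is
  available via `top_hits(..., prefilter=False)`.
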