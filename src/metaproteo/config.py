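"""Experiment configuration with defaults matching the published
thresholds (1% protein FDR, 20 hits, bit score > 80, consensus tolerance
> 80%, 'Other' pooling below 1%)."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml


class ConfigError(ValueError):
    """Invalid configuration (exit code 2 at the CLI)."""


@dataclass
class ExperimentConfig:
    seed: int = 0
    #: optional independent seed for the peptidome stage only (dependency
    #: isolation: changing it must leave the metagenome-derived DBs intact)
    peptidome_seed: int | None = None
    # community / reference store
    n_genera: int = 8
    n_present: int = 6
    community_skew: float = 1.0
    n_proteins_per_genus: int = 25
    n_families: int = 40
    within_family_identity: float = 0.9
    # reads
    n_reads: int = 2000
    read_length: int = 150
    error_rate: float = 0.005
    # trimming / gene calling / assembly
    min_mean_quality: float = 20.0
    min_read_length: int = 50
    min_orf_aa: int = 20
    min_overlap: int = 25
    drop_singletons: bool = True
    # taxon detection
    marker_min_hits: int = 5
    # peptidomes
    gel_free_spectra: int = 20000
    gel_based_spectra: int = 2000
    noise_fraction: float = 0.05
    detectability_bias: float = 0.5
    max_missed_cleavages: int = 2
    min_peptide_len: int = 6
    max_peptide_len: int = 40
    # search
    fdr: float = 0.01
    # annotation
    max_hits: int = 20
    min_bitscore: float = 80.0
    consensus_tolerance: float = 0.8
    prefilter_top: int = 200
    # analytics
    other_threshold: float = 1.0

    def validate(self) -> None:
        if not 0 < self.fdr < 1:
            raise ConfigError("fdr must be in (0, 1)")
        if not 0 < self.consensus_tolerance < 1:
            raise ConfigError("consensus_tolerance must be in (0, 1)")
        if self.n_present > self.n_genera:
            raise ConfigError("n_present cannot exceed n_genera")
        if not 0 <= self.noise_fraction < 0.5:
            raise ConfigError("noise_fraction must be in [0, 0.5)")
        if self.read_length < 30:
            raise ConfigError("read_length must be >= 30")

    # -- serialisation ----------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Fan a global seed out to a per-stage seed via a stable hash so each
    stage is independently reproducible."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)
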