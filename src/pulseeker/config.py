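"""Pipeline configuration.

Every threshold used anywhere in the pipeline lives in one dataclass so a
single YAML file fully determines a run. Defaults are the published values
of the Helgoland spring-bloom PUL survey workflow.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # domain-hit filtering (dbCAN-parser conventions)
    min_domain_coverage: float = 0.30   # aligned model positions / model length
    evalue_long: float = 1e-5           # i-evalue cap, alignments > short_ali_len residues
    evalue_short: float = 1e-3          # i-evalue cap, short alignments
    short_ali_len: int = 80             # residues

    # CAZyme confirmation (similarity-search second tier)
    cazy_min_identity: float = 30.0     # percent
    cazy_min_qcov: float = 0.40         # fraction of query aligned
    cazy_max_evalue: float = 1e-20

    # locus extraction
    max_gap: int = 10                   # markers chain when < max_gap genes lie between them
    min_markers: int = 3

    # MinHash sketching / species clustering
    kmer_size: int = 21
    sketch_size: int = 1000
    hash_seed: int = 42
    mash_threshold: float = 0.05        # same-species distance (~>=95% ANI)
    linkage: str = "single"             # or "complete"

    # MAG quality gates
    min_completeness: float = 70.0      # percent
    max_contamination_singleton: float = 10.0

    # abundance flags (RPKM)
    rpkm_single: float = 5.0            # exceeded at any one time-point
    rpkm_total: float = 38.0            # exceeded summed over all time-points

    # SusC/D dereplication and expression linking
    nt_cluster_identity: float = 95.0   # percent, nucleotide
    aa_link_identity: float = 90.0      # percent, amino acid
    min_metagenomes: int = 4
    alt_metagenomes: int = 3            # suffices with proteome support

    # substrate classification
    relaxed_laminarin_c: bool = False   # enable GH5_46+GH30_1 variant-C rule without GH16

    # proteomics
    duplicate_merge: str = "mean"       # technical duplicates: "mean" or "sum"

    def validate(self) -> None:
        if not 0 <= self.min_domain_coverage <= 1:
            raise ValueError("min_domain_coverage must be in [0, 1]")
        for name in ("evalue_long", "evalue_short", "cazy_max_evalue"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.cazy_min_identity <= 100:
            raise ValueError("cazy_min_identity must be in [0, 100]")
        if not 0 <= self.cazy_min_qcov <= 1:
            raise ValueError("cazy_min_qcov must be in [0, 1]")
        if self.max_gap < 1 or self.min_markers < 1:
            raise ValueError("max_gap and min_markers must be >= 1")
        if self.kmer_size < 1 or self.kmer_size > 31:
            raise ValueError("kmer_size must be in [1, 31]")
        if self.sketch_size < 1:
            raise ValueError("sketch_size must be >= 1")
        if not 0 <= self.mash_threshold <= 1:
            raise ValueError("mash_threshold must be in [0, 1]")
        if self.linkage not in ("single", "complete"):
            raise ValueError("linkage must be 'single' or 'complete'")
        if not 0 <= self.min_completeness <= 100:
            raise ValueError("min_completeness must be in [0, 100]")
        if self.max_contamination_singleton < 0:
            raise ValueError("max_contamination_singleton must be >= 0")
        if self.rpkm_single < 0 or self.rpkm_total < 0:
            raise ValueError("RPKM flags must be >= 0")
        for name in ("nt_cluster_identity", "aa_link_identity"):
            if not 0 <= getattr(self, name) <= 100:
                raise ValueError(f"{name} must be in [0, 100]")
        if self.min_metagenomes < 1 or self.alt_metagenomes < 1:
            raise ValueError("metagenome-count criteria must be >= 1")
        if self.duplicate_merge not in ("mean", "sum"):
            raise ValueError("duplicate_merge must be 'mean' or 'sum'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Short stable hash of the configuration, stamped into output headers."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
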