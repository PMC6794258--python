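"""Synthetic inputs with planted ground truth.

Every pipeline stage is exercisable without external data: this module
generates random genomes and mutated copies at known divergence (for
sketching/ANI checks), contig gene tables carrying planted PULs built from
the ten recurring substrate-pattern templates plus decoy loci that each
violate exactly one retention rule, the raw domain- and similarity-hit
tables that re-derive the planted role labels through the annotation
filters, and multinomial read-count / spectral-count matrices with known
true abundances. All randomness flows from one recorded seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    SULFATASE_MODEL,
    SUSC_MODEL,
    SUSD_MODELS,
    DomainHit,
    GeneRecord,
    GeneRole,
    SimilarityHit,
    is_cazy_family,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# gene composition of the ten recurring PUL patterns; tuples are features of
# one gene (a gene may carry several families / a sulfatase domain)
TEMPLATES: dict[str, dict] = {
    "beta_glucan_A": {
        "label": "beta-glucan/laminarin",
        "genes": [("susC",), ("susD",), ("GH16",), ("GH3",)],
    },
    "beta_glucan_B": {
        "label": "beta-glucan/laminarin",
        "genes": [("susC",), ("susD",), ("GH16",), ("GH30_1",), ("GH17",), ("GH17",)],
    },
    "beta_glucan_C": {
        "label": "beta-glucan/laminarin",
        "genes": [("susC",), ("susD",), ("GH5_46", "CBM6"), ("GH16",)],
    },
    "alpha_glucan_simple": {
        "label": "alpha-glucan",
        "genes": [("susC",), ("susD",), ("GH65",), ("GH13", "CBM48")],
    },
    "alpha_glucan_complex": {
        "label": "alpha-glucan",
        "genes": [("susC",), ("susD",), ("GH13",), ("GH13",), ("GH65",), ("GH43_12",)],
    },
    "mannose_sulfated": {
        "label": "alpha-mannose-rich",
        "genes": [
            ("susC",), ("susD",), ("GH92",), ("GH92",), ("GH92",),
            ("sulfatase",), ("sulfatase",), ("sulfatase",), ("GH2",), ("GH43_2",),
        ],
    },
    "mannose_sulfatase_free": {
        "label": "alpha-mannose-rich",
        "genes": [("susC",), ("susD",), ("GH92",), ("GH130",), ("GH20",), ("GH18",), ("CE2",)],
    },
    "sulfated_xylan_1": {
        "label": "sulfated xylan",
        "genes": [("susC",), ("susD",), ("GH10", "sulfatase"), ("GH3",), ("sulfatase",), ("sulfatase",)],
    },
    "sulfated_xylan_2": {
        "label": "sulfated xylan",
        "genes": [
            ("susC",), ("susD",), ("GH30",), ("sulfatase",), ("sulfatase",),
            ("sulfatase",), ("PL9", "CBM22"), ("GH10",), ("GH43_1",),
        ],
    },
    "alginate": {
        "label": "alginate",
        "genes": [("susC",), ("susD",), ("PL6",), ("PL7",), ("PL17",)],
    },
}

# decoys violate exactly one retention rule each
DECOY_MODES: dict[str, list[tuple]] = {
    "no_suscd": [("GH16",), ("GH3",), ("sulfatase",)],
    "single_degradative": [("susC",), ("susD",), ("GH16",), ("CE2",)],
    "wide_gap": [("susC",), ("susD",), ("GH16",), ("GH3",)],  # markers spaced 10 genes apart
    "gt_only": [("GT2",), ("GT4",), ("GT2",)],
}

_MODEL_LENGTHS = {
    SUSC_MODEL: 900,
    SULFATASE_MODEL: 350,
    "PF07980": 450,
    "PF12741": 300,
    "PF14322": 250,
    "PF12771": 150,
}


def model_length(model_id: str) -> int:
    return _MODEL_LENGTHS.get(model_id, 300)


@dataclass
class TruthSet:
    """Planted ground truth addressing every synthetic item by id."""

    seed: int
    planted_puls: list = field(default_factory=list)   # dicts: contig_id, span, template, label
    decoys: list = field(default_factory=list)          # dicts: contig_id, mode
    genome_pairs: list = field(default_factory=list)    # dicts: pair_id, divergence, realized_ani
    true_abundances: dict = field(default_factory=dict)  # mag -> {sample: rel. abundance}
    true_clusters: dict = field(default_factory=dict)    # mag -> species id

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            return cls(**json.load(fh))


def make_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """I.i.d. random nucleotide sequence with expected GC content ``gc``."""
    if length <= 0:
        raise ValueError("length must be > 0")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def mutate_genome(sequence: str, divergence: float, seed: int = 0) -> tuple[str, float]:
    """Substitute each site independently with probability ``divergence``.

    Substitutions always change the base. Returns (mutated sequence,
    realized divergence = substituted fraction).
    """
    if not 0 <= divergence < 0.75:
        raise ValueError("divergence must be in [0, 0.75)")
    rng = np.random.default_rng(seed)
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    idx = lut[codes]
    hit = rng.random(len(sequence)) < divergence
    shifts = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
    idx[hit] = (idx[hit] + shifts) % 4
    return _BASES[idx].tobytes().decode("ascii"), float(hit.sum()) / len(sequence)


@dataclass
class SyntheticCorpus:
    """A planted-PUL gene corpus plus the raw evidence tables that re-derive it."""

    genes: list                    # GeneRecord
    roles: list                    # GeneRole (planted truth labels)
    domain_hits: list              # DomainHit (raw, pre-filter)
    sim_hits: list                 # SimilarityHit (raw)
    truth: TruthSet

    def contigs(self) -> dict[str, tuple[list, list]]:
        """Per-contig (gene records, truth roles) in gene order, as the
        locus caller consumes them."""
        out: dict[str, tuple[list, list]] = {}
        for g, r in zip(self.genes, self.roles):
            out.setdefault(g.contig_id, ([], []))
            out[g.contig_id][0].append(g)
            out[g.contig_id][1].append(r)
        return out


class _ContigBuilder:
    def __init__(self, contig_id: str, rng: np.random.Generator):
        self.contig_id = contig_id
        self.rng = rng
        self.genes: list[GeneRecord] = []
        self.roles: list[GeneRole] = []
        self.domain_hits: list[DomainHit] = []
        self.sim_hits: list[SimilarityHit] = []
        self._pos = 1

    def _next_record(self, aa_length: int) -> GeneRecord:
        idx = len(self.genes)
        start = self._pos
        end = start + aa_length * 3 + 2
        self._pos = end + 51
        rec = GeneRecord(
            contig_id=self.contig_id,
            gene_index=idx,
            gene_id=f"{self.contig_id}_g{idx:03d}",
            start=start,
            end=end,
            strand="+" if self.rng.random() < 0.5 else "-",
            aa_length=aa_length,
        )
        self.genes.append(rec)
        return rec

    def add_background(self, n: int, noise_rate: float = 0.0) -> None:
        for _ in range(n):
            rec = self._next_record(int(self.rng.integers(80, 400)))
            self.roles.append(GeneRole(gene_id=rec.gene_id))
            if noise_rate and self.rng.random() < noise_rate:
                self._add_noise_hit(rec)

    def _add_noise_hit(self, rec: GeneRecord) -> None:
        """Sub-threshold evidence that every filter tier must reject."""
        kind = int(self.rng.integers(3))
        if kind == 0:  # fails the 30% model-coverage rule
            self.domain_hits.append(
                DomainHit(rec.gene_id, "GH13", 300, 1, 60, 1e-30, 80.0, q_from=1, q_to=60)
            )
        elif kind == 1:  # long alignment, i-evalue above the 1e-5 tier
            self.domain_hits.append(
                DomainHit(rec.gene_id, "GH16", 300, 1, 120, 1e-4, 30.0, q_from=1, q_to=120)
            )
        else:  # good profile hit but similarity support below 30% identity
            self.domain_hits.append(
                DomainHit(rec.gene_id, "GH2", 300, 1, 280, 1e-30, 200.0, q_from=1, q_to=280)
            )
            self.sim_hits.append(SimilarityHit(rec.gene_id, "GH2", 20.0, 0.8, 1e-50))

    def add_role_gene(self, features: tuple) -> None:
        """One marker gene with passing evidence for every feature."""
        models = []
        for feat in features:
            if feat == "susC":
                models.append(SUSC_MODEL)
            elif feat == "susD":
                models.append(sorted(SUSD_MODELS)[0])
            elif feat == "sulfatase":
                models.append(SULFATASE_MODEL)
            else:
                models.append(feat)
        total = sum(model_length(m) for m in models)
        aa_length = total + 40 * (len(models) + 1)

        rec = self._next_record(aa_length)
        role = GeneRole(gene_id=rec.gene_id)
        q = 40
        for feat, model in zip(features, models):
            mlen = model_length(model)
            self.domain_hits.append(
                DomainHit(rec.gene_id, model, mlen, 1, mlen, 1e-40, 300.0,
                          q_from=q + 1, q_to=q + mlen)
            )
            q += mlen + 40
            if feat in ("susC", "susD", "sulfatase"):
                role.roles.add(feat)
            else:
                self.sim_hits.append(SimilarityHit(rec.gene_id, feat, 60.0, 0.8, 1e-50))
                role.roles.add("cazyme")
                role.families.append(feat)
        self.roles.append(role)


def plant_puls(
    template_names: Sequence[str],
    decoy_modes: Sequence[str] = (),
    *,
    background_genes_per_contig: int = 20,
    noise_rate: float = 0.3,
    seed: int = 0,
) -> SyntheticCorpus:
    """Build a corpus with one planted locus or decoy per contig.

    Each entry of ``template_names`` plants one PUL of that pattern on its
    own contig, surrounded by role-less background genes (a fraction
    ``noise_rate`` of which carry sub-threshold evidence). Each entry of
    ``decoy_modes`` plants a near-miss locus violating exactly one
    retention rule. Raw domain/similarity hit tables are emitted alongside
    the truth labels so the annotation filters can re-derive the roles.
    """
    for name in template_names:
        if name not in TEMPLATES:
            raise ValueError(f"unknown template {name!r}")
    for mode in decoy_modes:
        if mode not in DECOY_MODES:
            raise ValueError(f"unknown decoy mode {mode!r}")
    if background_genes_per_contig < 6:
        raise ValueError("need at least 6 background genes per contig")

    rng = np.random.default_rng(seed)
    truth = TruthSet(seed=seed)
    genes: list[GeneRecord] = []
    roles: list[GeneRole] = []
    dhits: list[DomainHit] = []
    shits: list[SimilarityHit] = []
    n_contig = 0

    def finish(b: _ContigBuilder):
        genes.extend(b.genes)
        roles.extend(b.roles)
        dhits.extend(b.domain_hits)
        shits.extend(b.sim_hits)

    for name in template_names:
        b = _ContigBuilder(f"contig_{n_contig:04d}", rng)
        n_contig += 1
        n_before = int(rng.integers(2, background_genes_per_contig - 2))
        b.add_background(n_before, noise_rate)
        first = len(b.genes)
        for features in TEMPLATES[name]["genes"]:
            b.add_role_gene(features)
        last = len(b.genes) - 1
        b.add_background(background_genes_per_contig - n_before, noise_rate)
        truth.planted_puls.append(
            {
                "contig_id": b.contig_id,
                "first_index": first,
                "last_index": last,
                "template": name,
                "label": TEMPLATES[name]["label"],
            }
        )
        finish(b)

    for mode in decoy_modes:
        b = _ContigBuilder(f"contig_{n_contig:04d}", rng)
        n_contig += 1
        if mode == "wide_gap":
            b.add_background(2, noise_rate)
            for i, features in enumerate(DECOY_MODES[mode]):
                if i:
                    b.add_background(10, 0.0)  # exactly ten genes between markers
                b.add_role_gene(features)
            b.add_background(2, noise_rate)
        else:
            n_before = int(rng.integers(2, background_genes_per_contig - 2))
            b.add_background(n_before, noise_rate)
            for features in DECOY_MODES[mode]:
                b.add_role_gene(features)
            b.add_background(background_genes_per_contig - n_before, noise_rate)
        truth.decoys.append({"contig_id": b.contig_id, "mode": mode})
        finish(b)

    return SyntheticCorpus(genes=genes, roles=roles, domain_hits=dhits, sim_hits=shits, truth=truth)


def simulate_counts(
    true_abundances: pd.DataFrame | Mapping[str, Mapping[str, float]],
    genome_lengths: Mapping[str, float],
    total_reads: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial mapped-read counts per genome per sample.

    Sampling probabilities are proportional to relative abundance times
    genome length, the expectation of shotgun read recruitment.
    """
    if isinstance(true_abundances, pd.DataFrame):
        ab = true_abundances  # rows: mags, columns: samples
    else:
        ab = pd.DataFrame(true_abundances).T  # mapping mag -> {sample: abundance}
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    lens = np.array([genome_lengths[m] for m in ab.index], dtype=float)
    if np.any(lens <= 0):
        raise ValueError("genome lengths must be > 0")
    rng = np.random.default_rng(seed)
    out = {}
    for sample in ab.columns:
        w = ab[sample].to_numpy(dtype=float) * lens
        if np.any(w < 0):
            raise ValueError("negative abundance")
        if w.sum() == 0:
            raise ValueError(f"sample {sample}: probabilities not normalizable")
        out[sample] = rng.multinomial(total_reads, w / w.sum())
    return pd.DataFrame(out, index=ab.index)


def simulate_spectra(
    lengths: Mapping[str, float],
    true_expression: Mapping[str, float],
    total_spectra: int,
    seed: int = 0,
) -> pd.Series:
    """Multinomial spectral counts, probabilities ~ expression x length."""
    proteins = sorted(lengths)
    lens = np.array([lengths[p] for p in proteins], dtype=float)
    expr = np.array([true_expression[p] for p in proteins], dtype=float)
    if np.any(lens <= 0):
        raise ValueError("protein lengths must be > 0")
    if np.any(expr < 0):
        raise ValueError("negative expression")
    w = expr * lens
    if w.sum() == 0:
        raise ValueError("probabilities not normalizable")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(total_spectra, w / w.sum())
    return pd.Series(counts, index=proteins)
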