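"""SusC/SusD dereplication: identity clustering, representatives, taxonomy.

The locus caller yields many near-identical SusC- and SusD-like genes
because the same species is assembled independently from many samples.
These are collapsed by greedy centroid clustering at >= 95% nucleotide
identity (uclust-style: sequences processed in descending length order, a
sequence joins the first centroid it matches, otherwise founds a new
cluster). A cluster is promoted to *representative* status when its members
occur in at least four metagenomes, or in three metagenomes with expression
support from a metaproteome match at >= 90% amino-acid identity. Each
representative cluster is then given a taxonomy by majority vote over the
approximate-species (Mash) cluster assignments of its member genomes:
species-level when at least half of the assigned members agree (uniquely),
putative species when a strict plurality agrees, clade-level when all
assigned members at least share one clade, otherwise unassigned.

Pairwise identity is computed from a global (Needleman-Wunsch) alignment as
matches / alignment columns, so gaps count against identity.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def global_identity(a: str, b: str) -> float:
    """Percent identity of the global alignment of two sequences.

    Identity = matched columns / total alignment columns (matches,
    mismatches and gap columns all count toward the denominator).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    if a == b:
        return 100.0
    res = edlib.align(a, b, mode="NW", task="path")
    counts: Counter = Counter()
    for length, op in _CIGAR_RE.findall(res["cigar"]):
        counts[op] += int(length)
    columns = sum(counts.values())
    if "M" in counts:  # non-extended cigar: derive matches from edit distance
        indels = counts["I"] + counts["D"]
        matches = counts["M"] - (res["editDistance"] - indels)
    else:
        matches = counts["="]
    return 100.0 * matches / columns


@dataclass
class SusGene:
    """One SusC- or SusD-like gene from a called locus."""

    gene_id: str
    kind: str                      # "susC" or "susD"
    nt_sequence: str
    aa_sequence: str = ""
    source_metagenome: str = ""
    source_mag: str | None = None
    pul_id: str | None = None

    def __post_init__(self):
        if self.kind not in ("susC", "susD"):
            raise ValueError(f"{self.gene_id}: kind must be susC or susD")
        if not self.nt_sequence:
            raise ValueError(f"{self.gene_id}: empty nucleotide sequence")


@dataclass
class SusCDCluster:
    """A >= 95%-nucleotide-identity cluster of SusC- or SusD-like genes."""

    cluster_id: str
    kind: str
    members: list                  # SusGene, centroid first
    representative: str | None = None       # member gene_id, when promoted
    proteome_support: bool = False
    taxonomy: tuple = ("unassigned", None)  # (state, mash-cluster or clade)

    @property
    def n_metagenomes(self) -> int:
        return len({m.source_metagenome for m in self.members})

    @property
    def is_representative(self) -> bool:
        return self.representative is not None

    @property
    def centroid(self) -> SusGene:
        return self.members[0]


def cluster_95nt(genes: Sequence[SusGene], *, min_identity: float = 95.0) -> list[SusCDCluster]:
    """Greedy centroid clustering of same-kind genes at >= min_identity %nt.

    Deterministic: genes are processed in descending nucleotide length, ties
    by gene id; a gene joins the first existing cluster (in founding order)
    whose centroid it matches, else founds a new cluster.
    """
    if not genes:
        return []
    kinds = {g.kind for g in genes}
    if len(kinds) > 1:
        raise ValueError(f"mixed gene kinds in one clustering run: {sorted(kinds)}")
    kind = kinds.pop()

    ordered = sorted(genes, key=lambda g: (-len(g.nt_sequence), g.gene_id))
    clusters: list[list[SusGene]] = []
    for gene in ordered:
        for members in clusters:
            if global_identity(gene.nt_sequence, members[0].nt_sequence) >= min_identity:
                members.append(gene)
                break
        else:
            clusters.append([gene])
    return [
        SusCDCluster(cluster_id=f"{kind}_c{i + 1}", kind=kind, members=members)
        for i, members in enumerate(clusters)
    ]


def select_representatives(
    clusters: Sequence[SusCDCluster],
    proteome_hits: Sequence[tuple[str, str, float]] = (),
    *,
    min_metagenomes: int = 4,
    alt_metagenomes: int = 3,
    min_aa_identity: float = 90.0,
    mag_completeness: Mapping[str, float] | None = None,
) -> list[SusCDCluster]:
    """Promote clusters to representative status.

    A cluster qualifies with members from >= min_metagenomes distinct
    metagenomes, or from >= alt_metagenomes when a metaproteome protein
    matches it at >= min_aa_identity (proteome support). The representative
    member is the one from the most complete source genome (ties: longest
    sequence, then lexicographic gene id); ``proteome_hits`` are
    (protein_id, cluster_id, aa_identity) triples.
    """
    supported = {
        cluster_id
        for _, cluster_id, ident in proteome_hits
        if ident >= min_aa_identity
    }
    comp = mag_completeness or {}
    out = []
    for c in clusters:
        has_support = c.cluster_id in supported
        qualifies = c.n_metagenomes >= min_metagenomes or (
            c.n_metagenomes >= alt_metagenomes and has_support
        )
        rep = None
        if qualifies:
            ranked = sorted(
                c.members,
                key=lambda m: (
                    -comp.get(m.source_mag or "", 0.0),
                    -len(m.nt_sequence),
                    m.gene_id,
                ),
            )
            rep = ranked[0].gene_id
        out.append(
            SusCDCluster(
                cluster_id=c.cluster_id,
                kind=c.kind,
                members=list(c.members),
                representative=rep,
                proteome_support=has_support,
                taxonomy=c.taxonomy,
            )
        )
    return out


def vote_taxonomy(
    cluster: SusCDCluster,
    mag_assignments: Mapping[str, str],
    clade_map: Mapping[str, str] | None = None,
) -> tuple:
    """Vote a taxonomy for one cluster from its members' Mash-clusters.

    Members whose source genome has no Mash-cluster assignment are excluded
    from the denominator. Outcomes, tried in order:

    - ("assigned", mc): one Mash-cluster holds >= half of the votes and is
      the unique maximum;
    - ("putative", mc): a strict plurality below half;
    - ("clade", name): all voted Mash-clusters share one clade;
    - ("unassigned", None) otherwise.
    """
    votes = Counter(
        mag_assignments[m.source_mag]
        for m in cluster.members
        if m.source_mag is not None and m.source_mag in mag_assignments
    )
    if not votes:
        return ("unassigned", None)
    n = sum(votes.values())
    ranked = votes.most_common()
    top_mc, top_n = min(
        ((mc, c) for mc, c in ranked if c == ranked[0][1]), key=lambda t: t[0]
    )
    unique_top = sum(1 for _, c in ranked if c == ranked[0][1]) == 1
    if unique_top and 2 * top_n >= n:
        return ("assigned", top_mc)
    if unique_top:
        return ("putative", top_mc)
    if clade_map:
        clades = {clade_map.get(mc) for mc in votes}
        if len(clades) == 1 and None not in clades:
            return ("clade", clades.pop())
    return ("unassigned", None)


def assign_taxonomies(
    clusters: Sequence[SusCDCluster],
    mag_assignments: Mapping[str, str],
    clade_map: Mapping[str, str] | None = None,
) -> list[SusCDCluster]:
    out = []
    for c in clusters:
        out.append(
            SusCDCluster(
                cluster_id=c.cluster_id,
                kind=c.kind,
                members=list(c.members),
                representative=c.representative,
                proteome_support=c.proteome_support,
                taxonomy=vote_taxonomy(c, mag_assignments, clade_map),
            )
        )
    return out
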