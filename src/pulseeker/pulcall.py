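"""PUL extraction from ordered, role-annotated gene tables.

A candidate locus is a maximal chain of marker genes (sulfatases, confirmed
CAZymes, SusC- or SusD-like genes) on one contig in which consecutive markers
have fewer than ``max_gap`` non-marker genes between them, containing at
least ``min_markers`` markers and not consisting exclusively of
glycosyltransferase-only genes. A candidate is retained as a PUL when it
carries at least one susC- or susD-like gene and at least two genes with a
confirmed degradative family (GH or PL; CE/GT/CBM do not count).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .annotation import GeneRecord, GeneRole, family_clan
from .config import PipelineConfig
from .substrates import SubstrateCall, SubstrateRule, classify_substrate, load_rules


@dataclass
class PUL:
    """A called polysaccharide utilization locus."""

    contig_id: str
    first_index: int
    last_index: int
    marker_genes: list            # GeneRole, in gene order
    susCD_pairs: list = field(default_factory=list)   # adjacent (index_i, index_j) pairs
    degradative_count: int = 0    # genes carrying a confirmed GH or PL family
    substrate: SubstrateCall | None = None
    touches_contig_edge: bool = False

    @property
    def gene_span(self) -> tuple[int, int]:
        return (self.first_index, self.last_index)

    def feature_counts(self) -> Counter:
        """Family/role multiset used by substrate classification.

        Each confirmed family counts once per carrying gene; the "sulfatase"
        token counts genes with the sulfatase role.
        """
        counts: Counter = Counter()
        for _, role in self.marker_genes:
            for fam in role.families:
                counts[fam] += 1
            if "sulfatase" in role.roles:
                counts["sulfatase"] += 1
        return counts

    def validate(self) -> None:
        roles = set()
        for _, r in self.marker_genes:
            roles |= r.roles
        if not roles & {"susC", "susD"}:
            raise AssertionError("PUL without susC/susD gene")
        if self.degradative_count < 2:
            raise AssertionError("PUL with fewer than two degradative CAZymes")
        if len(self.marker_genes) < 3:
            raise AssertionError("PUL with fewer than three marker genes")
        if all(r.is_gt_only for _, r in self.marker_genes):
            raise AssertionError("PUL markers exclusively glycosyltransferases")


@dataclass
class CandidateLocus:
    contig_id: str
    markers: list                 # (gene_index, GeneRole)

    @property
    def first_index(self) -> int:
        return self.markers[0][0]

    @property
    def last_index(self) -> int:
        return self.markers[-1][0]


def chain_markers(
    genes: Sequence[tuple[int, GeneRole]] | Sequence[GeneRole],
    *,
    contig_id: str = "",
    max_gap: int = 10,
    min_markers: int = 3,
) -> list[CandidateLocus]:
    """Chain marker genes into candidate loci on one contig.

    ``genes`` is the complete ordered gene list for the contig, either as
    GeneRole objects (indices taken as positions) or as (gene_index, GeneRole)
    pairs with consecutive indices. Two consecutive markers belong to the same
    chain when strictly fewer than ``max_gap`` genes lie between them. Chains
    of fewer than ``min_markers`` markers, and chains whose markers are all
    GT-only, are discarded.
    """
    indexed: list[tuple[int, GeneRole]] = []
    for i, item in enumerate(genes):
        if isinstance(item, GeneRole):
            indexed.append((i, item))
        else:
            indexed.append((int(item[0]), item[1]))
    for (a, _), (b, _) in zip(indexed, indexed[1:]):
        if b != a + 1:
            raise ValueError("gene list must be ordered with consecutive indices")

    markers = [(i, r) for i, r in indexed if r.is_marker]
    chains: list[list[tuple[int, GeneRole]]] = []
    for idx, role in markers:
        if chains and idx - chains[-1][-1][0] - 1 < max_gap:
            chains[-1].append((idx, role))
        else:
            chains.append([(idx, role)])

    out = []
    for chain in chains:
        if len(chain) < min_markers:
            continue
        if all(r.is_gt_only for _, r in chain):
            continue
        out.append(CandidateLocus(contig_id=contig_id, markers=chain))
    return out


def filter_candidates(candidates: Sequence[CandidateLocus], *, n_genes_on_contig: int | None = None) -> list[PUL]:
    """Retain candidates with a susC/D gene and >=2 degradative CAZyme genes."""
    puls = []
    for cand in candidates:
        roles_by_index = dict(cand.markers)
        has_suscd = any(r.roles & {"susC", "susD"} for r in roles_by_index.values())
        degradative = sum(
            1
            for r in roles_by_index.values()
            if any(family_clan(f) in ("GH", "PL") for f in r.families)
        )
        if not has_suscd or degradative < 2:
            continue

        pairs = []
        for i, r in cand.markers:
            nxt = roles_by_index.get(i + 1)
            if nxt is None:
                continue
            if ("susC" in r.roles and "susD" in nxt.roles) or (
                "susD" in r.roles and "susC" in nxt.roles
            ):
                pairs.append((i, i + 1))

        touches = cand.first_index == 0 or (
            n_genes_on_contig is not None and cand.last_index == n_genes_on_contig - 1
        )
        puls.append(
            PUL(
                contig_id=cand.contig_id,
                first_index=cand.first_index,
                last_index=cand.last_index,
                marker_genes=list(cand.markers),
                susCD_pairs=pairs,
                degradative_count=degradative,
                touches_contig_edge=touches,
            )
        )
    return puls


def call_puls(
    contigs: dict[str, tuple[Sequence[GeneRecord], Sequence[GeneRole]]],
    config: PipelineConfig | None = None,
    rules: list[SubstrateRule] | None = None,
) -> list[PUL]:
    """Run locus extraction, retention filtering and substrate classification.

    ``contigs`` maps contig id to its ordered (gene records, gene roles);
    PULs are reported in contig order, then by span. Every reported PUL
    satisfies the locus invariants.
    """
    config = config or PipelineConfig()
    if rules is None:
        rules = load_rules()

    all_puls: list[PUL] = []
    for contig_id in sorted(contigs):
        records, roles = contigs[contig_id]
        if len(records) != len(roles):
            raise ValueError(f"{contig_id}: gene records and roles differ in length")
        indexed = [(g.gene_index, r) for g, r in zip(records, roles)]
        candidates = chain_markers(
            indexed, contig_id=contig_id, max_gap=config.max_gap, min_markers=config.min_markers
        )
        puls = filter_candidates(candidates, n_genes_on_contig=len(records))
        for pul in puls:
            pul.substrate = classify_substrate(pul, rules)
            pul.validate()
        all_puls.extend(sorted(puls, key=lambda p: p.first_index))
    return all_puls
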