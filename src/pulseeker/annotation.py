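"""Two-tier gene-role annotation.

Raw evidence comes from two kinds of searches run upstream (outside this
package): profile searches of predicted proteins against CAZyme-family,
sulfatase and SusC/SusD models, and protein-similarity searches against a
reference CAZyme database. This module turns those hit tables into per-gene
role labels:

1. Domain hits are filtered with dbCAN-parser-style rules: a minimum model
   coverage, alignment-length-tiered e-value cutoffs, and resolution of
   overlapping hits on the same gene (best e-value wins).
2. CAZyme family assignments additionally require a confirming similarity
   hit to the *same* family (identity, query-coverage and e-value gated).
   Only confirmed families feed locus prediction.
3. SusC, SusD and sulfatase roles come straight from the filtered profile
   hits to their dedicated models.

A gene may carry several roles at once — e.g. a sulfatase-domain-containing
GH10 is both a CAZyme and a sulfatase gene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

SUSD_MODELS = frozenset({"PF07980", "PF12741", "PF14322", "PF12771"})
SUSC_MODEL = "TIGR04056"
SULFATASE_MODEL = "PF00884"

_FAMILY_RE = re.compile(r"^(GH|PL|CE|GT|CBM|AA)(\d+)(?:_(\d+))?$")


@dataclass(frozen=True)
class GeneRecord:
    """One predicted gene on a contig, in gene-order coordinates."""

    contig_id: str
    gene_index: int          # 0-based, consecutive along the contig
    gene_id: str
    start: int               # 1-based nucleotide coordinate, inclusive
    end: int
    strand: str              # '+' or '-'
    aa_length: int

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        if self.aa_length <= 0:
            raise ValueError(f"{self.gene_id}: aa_length must be > 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class DomainHit:
    """A filtered or raw profile-search domain hit.

    ``ali_from``/``ali_to`` are model coordinates (used for the model-coverage
    rule); ``q_from``/``q_to`` are query-protein coordinates (used for overlap
    resolution between hits on the same gene) and default to the model
    coordinates when the source table does not provide them.
    """

    gene_id: str
    model_id: str
    model_length: int
    ali_from: int
    ali_to: int
    i_evalue: float
    bitscore: float
    q_from: int = 0
    q_to: int = 0

    def __post_init__(self):
        if not (1 <= self.ali_from <= self.ali_to <= self.model_length):
            raise ValueError(
                f"{self.gene_id}/{self.model_id}: need 1 <= ali_from <= ali_to <= model_length"
            )
        if self.i_evalue < 0:
            raise ValueError(f"{self.gene_id}/{self.model_id}: negative e-value")
        if self.q_from == 0 and self.q_to == 0:
            object.__setattr__(self, "q_from", self.ali_from)
            object.__setattr__(self, "q_to", self.ali_to)
        if self.q_from > self.q_to:
            raise ValueError(f"{self.gene_id}/{self.model_id}: q_from > q_to")

    @property
    def coverage(self) -> float:
        return (self.ali_to - self.ali_from + 1) / self.model_length

    @property
    def ali_length(self) -> int:
        return self.ali_to - self.ali_from + 1


@dataclass(frozen=True)
class SimilarityHit:
    """A protein-similarity hit against a reference CAZyme, family-resolved."""

    query_gene_id: str
    subject_family: str
    pct_identity: float      # 0-100
    query_coverage: float    # fraction of the query aligned, 0-1
    evalue: float

    def __post_init__(self):
        if not 0 <= self.pct_identity <= 100:
            raise ValueError(f"{self.query_gene_id}: pct_identity outside [0, 100]")
        if not 0 <= self.query_coverage <= 1:
            raise ValueError(f"{self.query_gene_id}: query_coverage outside [0, 1]")


@dataclass
class GeneRole:
    """Evidence-derived role labels for one gene."""

    gene_id: str
    roles: set = field(default_factory=set)      # subset of {susC, susD, sulfatase, cazyme}
    families: list = field(default_factory=list)  # confirmed CAZy families, e.g. GH5_46

    @property
    def is_gt_only(self) -> bool:
        """All confirmed families are glycosyltransferases and no other role."""
        return (
            bool(self.families)
            and all(family_clan(f) == "GT" for f in self.families)
            and self.roles == {"cazyme"}
        )

    @property
    def is_marker(self) -> bool:
        return bool(self.roles)


def parse_family(name: str) -> tuple[str, int, int | None]:
    """Split a CAZy family label into (clan, family number, subfamily or None)."""
    m = _FAMILY_RE.match(name)
    if m is None:
        raise ValueError(f"not a CAZy family label: {name!r}")
    clan, fam, sub = m.groups()
    return clan, int(fam), int(sub) if sub is not None else None


def family_clan(name: str) -> str:
    return parse_family(name)[0]


def is_cazy_family(name: str) -> bool:
    return _FAMILY_RE.match(name) is not None


def families_match(a: str, b: str) -> bool:
    """Same family; compared at subfamily level only when both carry one.

    GH5_46 vs GH5 → match (reference entries are often family-level);
    GH5_46 vs GH5_12 → no match; GH5 vs GH13 → no match.
    """
    ca, fa, sa = parse_family(a)
    cb, fb, sb = parse_family(b)
    if (ca, fa) != (cb, fb):
        return False
    if sa is not None and sb is not None:
        return sa == sb
    return True


def _strip_model_suffix(model_id: str) -> str:
    return model_id[:-4] if model_id.endswith(".hmm") else model_id


def filter_domain_hits(
    hits: Sequence[DomainHit],
    genes: Sequence[GeneRecord] | None = None,
    *,
    min_coverage: float = 0.30,
    evalue_long: float = 1e-5,
    evalue_short: float = 1e-3,
    short_ali_len: int = 80,
) -> list[DomainHit]:
    """Apply coverage, tiered e-value and same-gene overlap filtering.

    A hit is kept when its aligned model region covers >= ``min_coverage`` of
    the model and its independent e-value passes the tier for its alignment
    length (<= ``evalue_long`` for alignments longer than ``short_ali_len``
    residues, else <= ``evalue_short``). Among hits on the same gene whose
    query regions overlap by more than half of the shorter region, only the
    best hit survives (lowest i-evalue; ties: higher bitscore, then
    lexicographic model id).
    """
    if genes is not None:
        known = {g.gene_id for g in genes}
        for h in hits:
            if h.gene_id not in known:
                raise ValueError(f"domain hit references unknown gene {h.gene_id!r}")

    passing = []
    for h in hits:
        if not 0 <= h.coverage <= 1:
            raise ValueError(f"{h.gene_id}/{h.model_id}: malformed coverage {h.coverage}")
        if h.coverage < min_coverage:
            continue
        cap = evalue_long if h.ali_length > short_ali_len else evalue_short
        if h.i_evalue > cap:
            continue
        passing.append(h)

    by_gene: dict[str, list[DomainHit]] = {}
    for h in passing:
        by_gene.setdefault(h.gene_id, []).append(h)

    kept: list[DomainHit] = []
    for gene_hits in by_gene.values():
        ranked = sorted(gene_hits, key=lambda h: (h.i_evalue, -h.bitscore, h.model_id))
        accepted: list[DomainHit] = []
        for h in ranked:
            if not any(_overlaps_majority(h, a) for a in accepted):
                accepted.append(h)
        kept.extend(accepted)

    order = {id(h): i for i, h in enumerate(hits)}
    kept.sort(key=lambda h: order[id(h)])
    return kept


def _overlaps_majority(a: DomainHit, b: DomainHit) -> bool:
    """True when the query regions overlap by more than half of the shorter."""
    ov = min(a.q_to, b.q_to) - max(a.q_from, b.q_from) + 1
    if ov <= 0:
        return False
    shorter = min(a.q_to - a.q_from + 1, b.q_to - b.q_from + 1)
    return ov > 0.5 * shorter


def confirm_cazymes(
    hmm_hits: Sequence[DomainHit],
    sim_hits: Sequence[SimilarityHit],
    *,
    min_identity: float = 30.0,
    min_qcov: float = 0.40,
    max_evalue: float = 1e-20,
) -> list[tuple[str, str]]:
    """Confirm CAZy family calls with same-family similarity evidence.

    A (gene, family) pair from the filtered profile hits is confirmed only if
    the gene has at least one similarity hit to the same family passing all
    three thresholds. Only confirmed pairs feed locus prediction.
    """
    sims_by_gene: dict[str, list[SimilarityHit]] = {}
    for s in sim_hits:
        sims_by_gene.setdefault(s.query_gene_id, []).append(s)

    confirmed: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for h in hmm_hits:
        family = _strip_model_suffix(h.model_id)
        if not is_cazy_family(family):
            continue
        key = (h.gene_id, family)
        if key in seen:
            continue
        for s in sims_by_gene.get(h.gene_id, ()):
            if (
                is_cazy_family(s.subject_family)
                and families_match(family, s.subject_family)
                and s.pct_identity >= min_identity
                and s.query_coverage >= min_qcov
                and s.evalue <= max_evalue
            ):
                confirmed.append(key)
                seen.add(key)
                break
    return confirmed


def assign_roles(
    genes: Sequence[GeneRecord],
    confirmed_cazymes: Iterable[tuple[str, str]],
    filtered_hits: Sequence[DomainHit],
) -> list[GeneRole]:
    """Combine confirmed CAZymes and marker-model hits into per-gene roles."""
    roles = {g.gene_id: GeneRole(gene_id=g.gene_id) for g in genes}

    for h in filtered_hits:
        if h.gene_id not in roles:
            raise ValueError(f"filtered hit references unknown gene {h.gene_id!r}")
        model = _strip_model_suffix(h.model_id)
        if model in SUSD_MODELS:
            roles[h.gene_id].roles.add("susD")
        elif model == SUSC_MODEL:
            roles[h.gene_id].roles.add("susC")
        elif model == SULFATASE_MODEL:
            roles[h.gene_id].roles.add("sulfatase")

    for gene_id, family in confirmed_cazymes:
        if gene_id not in roles:
            raise ValueError(f"confirmed CAZyme references unknown gene {gene_id!r}")
        r = roles[gene_id]
        r.roles.add("cazyme")
        if family not in r.families:
            r.families.append(family)

    return [roles[g.gene_id] for g in genes]
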