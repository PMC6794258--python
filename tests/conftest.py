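import pytest

from pulseeker.annotation import DomainHit, GeneRecord, GeneRole, SimilarityHit
from pulseeker.substrates import load_rules


@pytest.fixture(scope="session")
def rules():
    return load_rules()


def make_gene(gene_id, idx=0, contig="c1", aa=300):
    return GeneRecord(
        contig_id=contig, gene_index=idx, gene_id=gene_id,
        start=1 + idx * 1000, end=idx * 1000 + aa * 3, strand="+", aa_length=aa,
    )


def role(gene_id, roles=(), families=()):
    return GeneRole(gene_id=gene_id, roles=set(roles), families=list(families))


def hit(gene_id, model, mlen=300, a=1, b=300, ev=1e-30, score=100.0, q=None):
    qf, qt = q if q else (a, b)
    return DomainHit(gene_id, model, mlen, a, b, ev, score, q_from=qf, q_to=qt)


def sim(gene_id, family, pid=60.0, qcov=0.8, ev=1e-50):
    return SimilarityHit(gene_id, family, pid, qcov, ev)


@pytest.fixture
def contig_roles():
    """Helper: build a contig's ordered role list from a sparse spec.

    spec maps gene index -> (roles, families); other indices are background.
    """

    def build(n_genes, spec):
        out = []
        for i in range(n_genes):
            roles_, fams = spec.get(i, ((), ()))
            out.append(role(f"g{i}", roles_, fams))
        return out

    return build
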