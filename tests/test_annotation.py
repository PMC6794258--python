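"""Two-tier annotation filtering: coverage/e-value gates, overlap
resolution, same-family similarity confirmation, role assignment."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulseeker.annotation import (
    assign_roles,
    confirm_cazymes,
    families_match,
    filter_domain_hits,
    parse_family,
)

from conftest import hit, make_gene, role, sim


class TestFamilyParsing:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("GH5_46", ("GH", 5, 46)),
            ("GH13", ("GH", 13, None)),
            ("PL17", ("PL", 17, None)),
            ("CBM22", ("CBM", 22, None)),
            ("GT2", ("GT", 2, None)),
        ],
    )
    def test_parse(self, name, expected):
        assert parse_family(name) == expected

    def test_reject_non_family(self):
        with pytest.raises(ValueError):
            parse_family("PF00884")

    @pytest.mark.parametrize(
        "a,b,match",
        [
            ("GH5_46", "GH5", True),    # family-level reference entry
            ("GH5_46", "GH5_46", True),
            ("GH5_46", "GH5_12", False),
            ("GH5", "GH13", False),
            ("GH30", "GH30_1", True),
        ],
    )
    def test_subfamily_matching(self, a, b, match):
        assert families_match(a, b) is match


class TestFilterDomainHits:
    def test_low_model_coverage_removed(self):
        # 71 aligned positions of a 300-long model: coverage 0.237 < 0.30
        h = hit("g1", "GH16", mlen=300, a=10, b=80, ev=1e-30)
        assert filter_domain_hits([h]) == []

    def test_empty_input(self):
        assert filter_domain_hits([]) == []

    def test_tiered_evalues(self):
        long_ok = hit("g1", "GH16", a=1, b=150, ev=9e-6)      # >80 aa, tier 1e-5
        long_bad = hit("g2", "GH16", a=1, b=150, ev=2e-5)
        short_ok = hit("g3", "GH16", mlen=150, a=1, b=60, ev=9e-4)  # <=80 aa, tier 1e-3
        short_bad = hit("g4", "GH16", mlen=150, a=1, b=60, ev=2e-3)
        kept = filter_domain_hits([long_ok, long_bad, short_ok, short_bad])
        assert [h.gene_id for h in kept] == ["g1", "g3"]

    def test_overlap_keeps_lowest_evalue(self):
        a = hit("g1", "GH16", ev=1e-10, q=(1, 200))
        b = hit("g1", "GH13", ev=1e-8, q=(50, 250))
        assert filter_domain_hits([a, b]) == [a]

    def test_minor_overlap_keeps_both(self):
        a = hit("g1", "GH16", ev=1e-10, q=(1, 200))
        b = hit("g1", "PF00884", mlen=350, a=1, b=300, ev=1e-8, q=(150, 450))
        # overlap 51 of shorter 200 -> not a majority
        assert len(filter_domain_hits([a, b])) == 2

    def test_overlap_tie_breaks(self):
        a = hit("g1", "GH3", ev=1e-10, score=90.0, q=(1, 200))
        b = hit("g1", "GH2", ev=1e-10, score=95.0, q=(1, 200))
        assert filter_domain_hits([a, b]) == [b]  # equal e-value, higher bitscore
        c = hit("g1", "GH2", ev=1e-10, score=90.0, q=(1, 200))
        assert filter_domain_hits([a, c]) == [c]  # full tie: lexicographic model id

    def test_unknown_gene_rejected(self):
        genes = [make_gene("g1")]
        with pytest.raises(ValueError, match="unknown gene"):
            filter_domain_hits([hit("gX", "GH16")], genes)

    def test_idempotent(self):
        hits = [
            hit("g1", "GH16", ev=1e-10, q=(1, 200)),
            hit("g1", "GH13", ev=1e-8, q=(50, 250)),
            hit("g2", "GH3", a=1, b=120, ev=1e-6),
            hit("g2", "PF00884", mlen=350, a=1, b=350, q=(200, 549)),
        ]
        once = filter_domain_hits(hits)
        assert filter_domain_hits(once) == once

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, data):
        """Greedy overlap resolution equals the independent best-first oracle
        on small random instances."""
        n = data.draw(st.integers(1, 12))
        hits = []
        for i in range(n):
            gene = data.draw(st.sampled_from(["g1", "g2"]))
            start = data.draw(st.integers(1, 150))
            length = data.draw(st.integers(95, 300))
            ev = data.draw(st.sampled_from([1e-30, 1e-10, 1e-6, 1e-4, 1e-2]))
            model = data.draw(st.sampled_from(["GH16", "GH13", "GH3", "PF00884"]))
            hits.append(
                hit(gene, model, mlen=300, a=1, b=min(300, length), ev=ev,
                    score=float(data.draw(st.integers(10, 200))),
                    q=(start, start + length - 1))
            )

        def oracle(hits):
            passing = [
                h for h in hits
                if h.coverage >= 0.30
                and h.i_evalue <= (1e-5 if h.ali_length > 80 else 1e-3)
            ]
            kept = []
            pool = sorted(passing, key=lambda h: (h.i_evalue, -h.bitscore, h.model_id))
            while pool:
                best = pool.pop(0)
                kept.append(best)
                pool = [
                    h for h in pool
                    if h.gene_id != best.gene_id
                    or min(h.q_to, best.q_to) - max(h.q_from, best.q_from) + 1
                    <= 0.5 * min(h.q_to - h.q_from + 1, best.q_to - best.q_from + 1)
                ]
            return {id(h) for h in kept}

        assert {id(h) for h in filter_domain_hits(hits)} == oracle(hits)


class TestConfirmCazymes:
    def test_confirmed_with_passing_similarity(self):
        assert confirm_cazymes([hit("g1", "GH16")], [sim("g1", "GH16", 45.0, 0.60, 1e-30)]) == [
            ("g1", "GH16")
        ]

    @pytest.mark.parametrize(
        "pid,qcov,ev",
        [(25.0, 0.60, 1e-30), (45.0, 0.30, 1e-30), (45.0, 0.60, 1e-10)],
    )
    def test_each_threshold_enforced(self, pid, qcov, ev):
        assert confirm_cazymes([hit("g1", "GH16")], [sim("g1", "GH16", pid, qcov, ev)]) == []

    def test_same_family_required(self):
        assert confirm_cazymes([hit("g1", "GH16")], [sim("g1", "GH13")]) == []

    def test_subfamily_hmm_vs_family_similarity(self):
        assert confirm_cazymes([hit("g1", "GH5_46")], [sim("g1", "GH5")]) == [("g1", "GH5_46")]

    def test_non_cazy_models_ignored(self):
        assert confirm_cazymes([hit("g1", "PF00884", mlen=350, b=300)], [sim("g1", "GH16")]) == []

    @given(
        pid=st.floats(30, 90), qcov=st.floats(0.4, 1.0),
        d_pid=st.floats(0, 30), d_qcov=st.floats(0, 0.4),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_threshold_monotonicity(self, pid, qcov, d_pid, d_qcov):
        """Raising identity/coverage thresholds never grows the confirmed set."""
        hmm = [hit("g1", "GH16"), hit("g2", "GH13")]
        sims = [sim("g1", "GH16", 45.0, 0.6), sim("g2", "GH13", 35.0, 0.5)]
        loose = set(confirm_cazymes(hmm, sims, min_identity=pid, min_qcov=qcov))
        tight = set(
            confirm_cazymes(hmm, sims, min_identity=pid + d_pid, min_qcov=min(1.0, qcov + d_qcov))
        )
        assert tight <= loose


class TestAssignRoles:
    def test_marker_models(self):
        genes = [make_gene("g1", 0), make_gene("g2", 1), make_gene("g3", 2)]
        filtered = [
            hit("g1", "PF00884", mlen=350, b=350),
            hit("g2", "TIGR04056", mlen=900, b=900),
            hit("g3", "PF12741", mlen=300, b=300),
        ]
        roles = assign_roles(genes, [], filtered)
        assert roles[0].roles == {"sulfatase"}
        assert roles[1].roles == {"susC"}
        assert roles[2].roles == {"susD"}

    def test_no_hits_empty_roles(self):
        roles = assign_roles([make_gene("g1")], [], [])
        assert roles[0].roles == set() and not roles[0].is_marker

    def test_gt_only(self):
        roles = assign_roles([make_gene("g1")], [("g1", "GT2")], [])
        assert roles[0].is_gt_only
        roles = assign_roles([make_gene("g1")], [("g1", "GT2"), ("g1", "GH16")], [])
        assert not roles[0].is_gt_only

    def test_multirole_sulfatase_cazyme(self):
        genes = [make_gene("g1")]
        filtered = [hit("g1", "PF00884", mlen=350, b=350)]
        roles = assign_roles(genes, [("g1", "GH10")], filtered)
        assert roles[0].roles == {"sulfatase", "cazyme"}
        assert roles[0].families == ["GH10"]
        assert not roles[0].is_gt_only
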