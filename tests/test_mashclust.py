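"""MinHash sketching, Mash distance, species clustering, quality gates."""

import numpy as np
import pandas as pd
import pytest

from pulseeker.mashclust import (
    MagQuality,
    MashCluster,
    Sketch,
    cluster_mags,
    distance_from_jaccard,
    distance_matrix,
    flag_abundant,
    mash_distance,
    pick_representatives,
    quality_filter,
    sketch,
    sketch_jaccard,
)
from pulseeker.synth import make_genome, mutate_genome


def revcomp(s):
    return s[::-1].translate(str.maketrans("ACGT", "TGCA"))


def exact_canonical_jaccard(a, b, k=21):
    """Brute-force Jaccard over canonical k-mer sets (oracle)."""
    ka = {min(a[i : i + k], revcomp(a[i : i + k])) for i in range(len(a) - k + 1)}
    kb = {min(b[i : i + k], revcomp(b[i : i + k])) for i in range(len(b) - k + 1)}
    return len(ka & kb) / len(ka | kb)


class TestSketch:
    def test_identical_sequences_identical_sketches(self):
        g = make_genome(5000, seed=1)
        assert np.array_equal(sketch(g).hashes, sketch(g).hashes)

    def test_sequence_of_length_k_single_hash(self):
        assert sketch("A" * 21).hashes.size == 1

    def test_random_10kb_fills_sketch(self):
        g = make_genome(10_000, seed=2)
        assert sketch(g, s=1000).hashes.size == 1000

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="shorter than k"):
            sketch("ACGT", k=21)

    def test_ambiguous_bases_skipped_and_counted(self):
        g = make_genome(1000, seed=3)
        noisy = g[:500] + "N" + g[501:]
        sk = sketch(noisy, s=5000)
        assert sk.n_skipped == 21  # one N invalidates 21 windows
        assert sketch(g, s=5000).hashes.size >= sk.hashes.size

    def test_strand_invariance(self):
        g = make_genome(3000, seed=4)
        assert np.array_equal(sketch(g).hashes, sketch(revcomp(g)).hashes)

    def test_seed_changes_hashes(self):
        g = make_genome(3000, seed=5)
        assert not np.array_equal(sketch(g, seed=1).hashes, sketch(g, seed=2).hashes)

    def test_json_round_trip(self):
        sk = sketch(make_genome(2000, seed=6), mag_id="m1")
        back = Sketch.from_dict(sk.to_dict())
        assert back.mag_id == "m1" and np.array_equal(back.hashes, sk.hashes)


class TestMashDistance:
    def test_identical_sketches_distance_zero(self):
        sk = sketch(make_genome(5000, seed=7))
        assert mash_distance(sk, sk) == 0.0

    def test_disjoint_sketches_distance_capped_at_one(self):
        a = sketch(make_genome(5000, seed=8))
        b = sketch(make_genome(5000, seed=9))
        d = mash_distance(a, b)
        assert d == 1.0 or d > 0.2  # unrelated genomes: j ~ 0

    def test_formula_value(self):
        # j = 0.212 at k = 21 sits exactly at the species threshold
        assert distance_from_jaccard(0.212, 21) == pytest.approx(0.0500, abs=2e-4)

    def test_symmetry(self):
        g = make_genome(5000, seed=10)
        m, _ = mutate_genome(g, 0.05, seed=11)
        a, b = sketch(g), sketch(m)
        assert mash_distance(a, b) == mash_distance(b, a)

    def test_mismatched_parameters_rejected(self):
        g = make_genome(2000, seed=12)
        with pytest.raises(ValueError, match="mismatched"):
            mash_distance(sketch(g, k=21), sketch(g, k=15))
        with pytest.raises(ValueError, match="mismatched"):
            mash_distance(sketch(g, seed=1), sketch(g, seed=2))

    @pytest.mark.parametrize("p", [0.01, 0.03, 0.05])
    def test_ani_recovery(self, p):
        """Mean distance over replicates tracks the planted divergence."""
        ds = []
        for i in range(20):
            g = make_genome(50_000, seed=1000 + i)
            m, _ = mutate_genome(g, p, seed=2000 + i)
            ds.append(mash_distance(sketch(g), sketch(m)))
        assert abs(float(np.mean(ds)) - p) <= 0.01

    def test_jaccard_estimate_vs_exact_oracle(self):
        g = make_genome(4000, seed=13)
        m, _ = mutate_genome(g, 0.02, seed=14)
        est = sketch_jaccard(sketch(g), sketch(m))
        assert abs(est - exact_canonical_jaccard(g, m)) <= 0.05


class TestClusterMags:
    def _dist(self, ids, pairs):
        df = pd.DataFrame(1.0, index=ids, columns=ids)
        np.fill_diagonal(df.values, 0.0)
        for a, b, d in pairs:
            df.loc[a, b] = df.loc[b, a] = d
        return df

    def test_all_close_one_cluster(self):
        df = self._dist(list("ABC"), [("A", "B", 0.01), ("A", "C", 0.01), ("B", "C", 0.01)])
        (c,) = cluster_mags(df)
        assert set(c.member_mag_ids) == {"A", "B", "C"}

    def test_single_linkage_chain(self):
        df = self._dist(list("ABC"), [("A", "B", 0.04), ("B", "C", 0.04), ("A", "C", 0.08)])
        (c,) = cluster_mags(df)
        assert set(c.member_mag_ids) == {"A", "B", "C"}

    def test_complete_linkage_splits_chain(self):
        df = self._dist(list("ABC"), [("A", "B", 0.04), ("B", "C", 0.04), ("A", "C", 0.08)])
        clusters = cluster_mags(df, linkage="complete")
        assert len(clusters) == 2

    def test_all_distant_all_singletons(self):
        df = self._dist(list("ABCD"), [])
        assert all(c.is_singleton for c in cluster_mags(df))

    def test_input_order_invariance(self):
        ids = ["m3", "m1", "m4", "m2"]
        df = self._dist(ids, [("m1", "m2", 0.02), ("m3", "m4", 0.03)])
        perm = ["m1", "m2", "m3", "m4"]
        a = cluster_mags(df)
        b = cluster_mags(df.loc[perm, perm])
        assert [(c.cluster_id, tuple(sorted(c.member_mag_ids))) for c in a] == [
            (c.cluster_id, tuple(sorted(c.member_mag_ids))) for c in b
        ]

    def test_asymmetric_matrix_rejected(self):
        df = self._dist(list("AB"), [])
        df.iloc[0, 1] = 0.01
        with pytest.raises(ValueError, match="symmetric"):
            cluster_mags(df)

    def test_distance_matrix_from_sketches(self):
        g = make_genome(5000, seed=20)
        m, _ = mutate_genome(g, 0.02, seed=21)
        sks = [sketch(g, mag_id="a"), sketch(m, mag_id="b")]
        df = distance_matrix(sks)
        assert df.loc["a", "a"] == 0.0
        assert df.loc["a", "b"] == df.loc["b", "a"] < 0.05


def q(mag, comp, cont=5.0):
    return MagQuality(mag, comp, cont)


class TestQualityGates:
    def test_multi_mag_cluster_without_two_complete_members_excluded(self):
        c = MashCluster("mc_1", ("A", "B", "C"))
        (out,) = quality_filter([c], [q("A", 65), q("B", 60), q("C", 55)])
        assert out.retained is False

    def test_multi_mag_cluster_with_two_at_boundary_retained(self):
        c = MashCluster("mc_1", ("A", "B", "C"))
        (out,) = quality_filter([c], [q("A", 70), q("B", 70), q("C", 10)])
        assert out.retained is True  # completeness 70 counts as >= 70

    def test_singleton_low_quality_excluded(self):
        (out,) = quality_filter([MashCluster("mc_1", ("A",))], [q("A", 50, 12)])
        assert out.retained is False

    def test_singleton_boundary_cases(self):
        # exactly at 70% completeness and 10% contamination: both conditions met
        (out,) = quality_filter([MashCluster("mc_1", ("A",))], [q("A", 70, 10)])
        assert out.retained is False
        # either condition alone is not enough
        (out,) = quality_filter([MashCluster("mc_1", ("A",))], [q("A", 71, 50)])
        assert out.retained is True
        (out,) = quality_filter([MashCluster("mc_1", ("A",))], [q("A", 30, 9.9)])
        assert out.retained is True

    def test_retained_singleton(self):
        (out,) = quality_filter([MashCluster("mc_1", ("A",))], [q("A", 80, 5)])
        assert out.retained is True

    def test_missing_quality_record_rejected(self):
        with pytest.raises(KeyError, match="quality record"):
            quality_filter([MashCluster("mc_1", ("A", "B"))], [q("A", 80)])


class TestRepresentatives:
    def test_top_two_by_completeness(self):
        c = MashCluster("mc_1", ("A", "B", "C"))
        assert pick_representatives(c, [q("A", 95), q("B", 90), q("C", 85)]) == ("A", "B")

    def test_singleton(self):
        assert pick_representatives(MashCluster("mc_1", ("A",)), [q("A", 80)]) == ("A",)

    def test_tie_broken_by_contamination_then_id(self):
        c = MashCluster("mc_1", ("A", "B", "C"))
        reps = pick_representatives(c, [q("A", 90, 2), q("B", 90, 1), q("C", 80, 0)])
        assert reps == ("B", "A")
        reps = pick_representatives(c, [q("A", 90, 1), q("B", 90, 1), q("C", 80, 0)])
        assert reps == ("A", "B")


class TestAbundanceFlag:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([6, 0, 0], True),       # one time-point above 5
            ([5, 5, 5], False),      # 5 is not exceeding; sum 15 <= 38
            ([1] * 38, False),       # sum exactly 38 is not exceeding
            ([1] * 39, True),        # sum 39 exceeds
            ([5.1], True),
            ([], False),             # no samples: treated as all-zero
            ([4, 4, 4, 4, 4, 4, 4, 4, 4, 3], True),  # sum 39 without any single > 5
        ],
    )
    def test_flag(self, values, expected):
        assert flag_abundant(values) is expected

    def test_negative_rpkm_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            flag_abundant([1.0, -0.1])
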