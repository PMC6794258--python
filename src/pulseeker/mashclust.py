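"""MinHash sketching, Mash distance and approximate-species clustering.

Genomes are reduced to bottom-``s`` MinHash sketches over canonical k-mers
(k = 21, s = 1000 by default). The Mash distance between two sketches is

    D = -(1/k) * ln(2j / (1 + j)),

with j the Jaccard index estimated from the shared fraction among the s
smallest hashes of the merged sketch (the union-sketch estimator), and
D defined as 1 when j = 0. Genomes within D <= 0.05 (about >= 95% average
nucleotide identity) are grouped into approximate-species clusters by
single-linkage connected components; clusters then pass completeness /
contamination quality gates, contribute up to two highest-completeness
representative genomes, and are flagged as abundant from per-sample RPKM.

The k-mer hash is the package's own: canonical k-mers are packed into 64-bit
integers (2 bits per base, so k <= 31) and passed through a
seed-parameterized splitmix64 finalizer, vectorized with numpy. The seed is
recorded in every sketch so results are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

_U64 = np.uint64
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _BASE_CODE[b] = i
    _BASE_CODE[b + 32] = i  # lowercase


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """splitmix64 avalanche finalizer, elementwise on uint64 (wrapping)."""
    x = (x + _U64(0x9E3779B97F4A7C15)).astype(_U64)
    x ^= x >> _U64(30)
    x = (x * _U64(0xBF58476D1CE4E5B9)).astype(_U64)
    x ^= x >> _U64(27)
    x = (x * _U64(0x94D049BB133111EB)).astype(_U64)
    x ^= x >> _U64(31)
    return x


def _seed_constant(seed: int) -> np.uint64:
    return _splitmix64(np.array([seed], dtype=_U64))[0]


def canonical_kmer_hashes(sequence: str, k: int, seed: int = 42) -> tuple[np.ndarray, int]:
    """Hash every valid canonical k-mer window of a sequence.

    Canonical = the lexicographically smaller of a k-mer and its reverse
    complement (A<C<G<T, so integer order equals lexicographic order).
    Windows containing non-ACGT characters are skipped; returns (unique
    hashes sorted ascending, number of skipped windows).
    """
    if k < 1 or k > 31:
        raise ValueError("k must be in [1, 31]")
    n = len(sequence)
    if n < k:
        raise ValueError(f"sequence length {n} shorter than k = {k}")
    codes = _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    bad = codes == 255
    m = n - k + 1

    cs = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(bad, out=cs[1:])
    valid = (cs[k:] - cs[:m]) == 0
    n_skipped = int(m - valid.sum())

    safe = np.where(bad, 0, codes).astype(_U64)
    comp = _U64(3) - safe
    fwd = np.zeros(m, dtype=_U64)
    rev = np.zeros(m, dtype=_U64)
    for j in range(k):
        fwd = (fwd << _U64(2)) | safe[j : j + m]
        rev = (rev << _U64(2)) | comp[k - 1 - j : k - 1 - j + m]
    canon = np.minimum(fwd, rev)[valid]
    hashes = _splitmix64(canon ^ _seed_constant(seed))
    return np.unique(hashes), n_skipped


@dataclass
class Sketch:
    """Bottom-s MinHash sketch of one genome."""

    mag_id: str
    k: int
    s: int
    seed: int
    hashes: np.ndarray            # sorted ascending, <= s values
    n_skipped: int = 0

    def to_dict(self) -> dict:
        return {
            "mag_id": self.mag_id,
            "k": self.k,
            "s": self.s,
            "seed": self.seed,
            "n_skipped": self.n_skipped,
            "hashes": [int(h) for h in self.hashes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Sketch":
        return cls(
            mag_id=d["mag_id"],
            k=int(d["k"]),
            s=int(d["s"]),
            seed=int(d["seed"]),
            n_skipped=int(d.get("n_skipped", 0)),
            hashes=np.array(sorted(d["hashes"]), dtype=_U64),
        )


def sketch(
    sequence: str | Sequence[str],
    *,
    mag_id: str = "",
    k: int = 21,
    s: int = 1000,
    seed: int = 42,
) -> Sketch:
    """Build the bottom-s sketch of a genome (string or list of contigs)."""
    contigs = [sequence] if isinstance(sequence, str) else list(sequence)
    if not contigs:
        raise ValueError("no sequence given")
    all_hashes = []
    skipped = 0
    for contig in contigs:
        h, ns = canonical_kmer_hashes(contig, k, seed)
        all_hashes.append(h)
        skipped += ns
    merged = np.unique(np.concatenate(all_hashes))
    return Sketch(mag_id=mag_id, k=k, s=s, seed=seed, hashes=merged[:s], n_skipped=skipped)


def distance_from_jaccard(j: float, k: int) -> float:
    """Mash distance for a Jaccard estimate j at k-mer size k (capped at 1)."""
    if j <= 0:
        return 1.0
    return min(1.0, -math.log(2.0 * j / (1.0 + j)) / k)


def sketch_jaccard(a: Sketch, b: Sketch) -> float:
    """Union-sketch Jaccard estimate: shared fraction among the s smallest
    hashes of the merged sketch."""
    if (a.k, a.s, a.seed) != (b.k, b.s, b.seed):
        raise ValueError("sketches have mismatched k, s or hash seed")
    merged = np.union1d(a.hashes, b.hashes)
    su = min(a.s, merged.size)
    sample = merged[:su]
    shared = int(np.sum(np.isin(sample, a.hashes) & np.isin(sample, b.hashes)))
    return shared / su


def mash_distance(a: Sketch, b: Sketch) -> float:
    return distance_from_jaccard(sketch_jaccard(a, b), a.k)


def distance_matrix(sketches: Sequence[Sketch]) -> pd.DataFrame:
    ids = [s.mag_id for s in sketches]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate mag_id among sketches")
    n = len(sketches)
    mat = np.zeros((n, n))
    for i in range(n):
        for jx in range(i + 1, n):
            d = mash_distance(sketches[i], sketches[jx])
            mat[i, jx] = mat[jx, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


@dataclass
class MagQuality:
    mag_id: str
    completeness: float   # percent
    contamination: float  # percent

    def __post_init__(self):
        if not 0 <= self.completeness <= 100:
            raise ValueError(f"{self.mag_id}: completeness outside [0, 100]")
        if self.contamination < 0:
            raise ValueError(f"{self.mag_id}: negative contamination")


@dataclass
class MashCluster:
    cluster_id: str
    member_mag_ids: tuple
    representatives: tuple = ()
    retained: bool | None = None
    abundant: bool | None = None

    @property
    def is_singleton(self) -> bool:
        return len(self.member_mag_ids) == 1


def cluster_mags(
    distances: pd.DataFrame, threshold: float = 0.05, *, linkage: str = "single"
) -> list[MashCluster]:
    """Group genomes into approximate-species clusters at D <= threshold.

    Single linkage (default) takes connected components of the graph whose
    edges are pairs at D <= threshold, matching the network depiction of
    Mash-clusters; "complete" uses complete-linkage hierarchical clustering
    cut at the threshold. Cluster ids mc_1, mc_2, ... are assigned in order
    of each cluster's lexicographically smallest member.
    """
    if list(distances.index) != list(distances.columns):
        raise ValueError("distance matrix index and columns differ")
    arr = distances.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal is not zero")

    ids = list(distances.index)
    if linkage == "single":
        g = nx.Graph()
        g.add_nodes_from(ids)
        n = len(ids)
        for i in range(n):
            for jx in range(i + 1, n):
                if arr[i, jx] <= threshold:
                    g.add_edge(ids[i], ids[jx])
        groups = [sorted(c) for c in nx.connected_components(g)]
    elif linkage == "complete":
        from scipy.cluster.hierarchy import fcluster, linkage as _linkage
        from scipy.spatial.distance import squareform

        if len(ids) == 1:
            groups = [[ids[0]]]
        else:
            condensed = squareform(arr, checks=False)
            labels = fcluster(_linkage(condensed, method="complete"), t=threshold, criterion="distance")
            bucket: dict[int, list[str]] = {}
            for mag, lab in zip(ids, labels):
                bucket.setdefault(int(lab), []).append(mag)
            groups = [sorted(v) for v in bucket.values()]
    else:
        raise ValueError("linkage must be 'single' or 'complete'")

    groups.sort(key=lambda g: g[0])
    return [
        MashCluster(cluster_id=f"mc_{i + 1}", member_mag_ids=tuple(members))
        for i, members in enumerate(groups)
    ]


def _quality_map(qualities) -> Mapping[str, MagQuality]:
    if isinstance(qualities, Mapping):
        return qualities
    return {q.mag_id: q for q in qualities}


def quality_filter(
    clusters: Sequence[MashCluster],
    qualities,
    *,
    min_completeness: float = 70.0,
    max_contamination_singleton: float = 10.0,
) -> list[MashCluster]:
    """Set the retained flag from completeness/contamination gates.

    Multi-genome clusters need at least two members at >= min_completeness;
    a singleton is dropped only when it is both <= min_completeness complete
    and >= max_contamination_singleton contaminated.
    """
    qmap = _quality_map(qualities)
    out = []
    for c in clusters:
        for m in c.member_mag_ids:
            if m not in qmap:
                raise KeyError(f"no quality record for MAG {m!r}")
        if c.is_singleton:
            q = qmap[c.member_mag_ids[0]]
            retained = not (
                q.completeness <= min_completeness
                and q.contamination >= max_contamination_singleton
            )
        else:
            n_good = sum(1 for m in c.member_mag_ids if qmap[m].completeness >= min_completeness)
            retained = n_good >= 2
        out.append(
            MashCluster(
                cluster_id=c.cluster_id,
                member_mag_ids=c.member_mag_ids,
                representatives=c.representatives,
                retained=retained,
                abundant=c.abundant,
            )
        )
    return out


def pick_representatives(cluster: MashCluster, qualities) -> tuple:
    """Up to two highest-completeness members (ties: lower contamination,
    then lexicographic mag id)."""
    qmap = _quality_map(qualities)
    ranked = sorted(
        cluster.member_mag_ids,
        key=lambda m: (-qmap[m].completeness, qmap[m].contamination, m),
    )
    return tuple(ranked[:2])


def flag_abundant(values: Iterable[float], *, single: float = 5.0, total: float = 38.0) -> bool:
    """Abundant iff any per-sample RPKM exceeds ``single`` or the sum over
    samples exceeds ``total`` (strict: equal is not exceeding)."""
    vals = [float(v) for v in values]
    if any(v < 0 for v in vals):
        raise ValueError("negative RPKM value")
    if not vals:
        return False
    return max(vals) > single or sum(vals) > total
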