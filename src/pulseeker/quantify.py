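"""Abundance (RPKM) and expression (%NSAF) quantitation.

Genome abundance per sample is reads per kilobase per million:

    RPKM = mapped_reads * 1e6 / (assembly_length_kbp * total_reads)

and a Mash-cluster's abundance is the mean RPKM of its (one or two)
representative genomes. Proteome expression uses percent normalized
spectral abundance factors,

    %NSAF_i = 100 * (SpC_i / L_i) / sum_j (SpC_j / L_j),

the length-normalized share of spectral counts in one experiment (a %NSAF
of 1 is 1% of all mass-adjusted spectral counts). Expressed proteins are
linked back to representative SusC/D clusters by best global amino-acid
identity at a >= 90% floor.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .derep import SusCDCluster, global_identity


def rpkm(mapped_reads: float, assembly_length_kbp: float, total_reads: float) -> float:
    """Reads per kilobase of genome per million sample reads."""
    if assembly_length_kbp <= 0:
        raise ValueError("assembly_length_kbp must be > 0")
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if mapped_reads < 0:
        raise ValueError("mapped_reads must be >= 0")
    if mapped_reads > total_reads:
        raise ValueError("mapped_reads exceeds total_reads")
    return mapped_reads * 1_000_000.0 / (assembly_length_kbp * total_reads)


def rpkm_matrix(
    counts: pd.DataFrame,
    assembly_lengths_kbp: Mapping[str, float],
    total_reads: Mapping[str, float],
) -> pd.DataFrame:
    """Per-genome, per-sample RPKM from a mapped-read count matrix.

    ``counts`` has genomes as rows and samples as columns; lengths are in
    kbp keyed by genome, totals keyed by sample.
    """
    missing = [m for m in counts.index if m not in assembly_lengths_kbp]
    if missing:
        raise KeyError(f"no assembly length for: {missing}")
    missing = [s for s in counts.columns if s not in total_reads]
    if missing:
        raise KeyError(f"no total read count for sample: {missing}")
    out = counts.astype(float).copy()
    for sample in out.columns:
        for mag in out.index:
            out.loc[mag, sample] = rpkm(
                counts.loc[mag, sample], assembly_lengths_kbp[mag], total_reads[sample]
            )
    return out


def cluster_abundance(representative_rpkms: Sequence[float]) -> float:
    """Mash-cluster abundance: mean RPKM of its 1-2 representatives."""
    vals = [float(v) for v in representative_rpkms]
    if not 1 <= len(vals) <= 2:
        raise ValueError("expected one or two representative RPKM values")
    return sum(vals) / len(vals)


def cluster_abundance_matrix(
    mag_rpkm: pd.DataFrame, representatives: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Per-cluster, per-sample abundance from representative-genome RPKM."""
    rows = {}
    for cluster_id, reps in representatives.items():
        missing = [r for r in reps if r not in mag_rpkm.index]
        if missing:
            raise KeyError(f"{cluster_id}: no RPKM rows for representatives {missing}")
        rows[cluster_id] = [
            cluster_abundance([mag_rpkm.loc[r, s] for r in reps]) for s in mag_rpkm.columns
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=mag_rpkm.columns)


def nsaf(spectral_counts: Sequence[float], lengths: Sequence[float]) -> np.ndarray:
    """Percent normalized spectral abundance factors for one experiment."""
    counts = np.asarray(spectral_counts, dtype=float)
    lens = np.asarray(lengths, dtype=float)
    if counts.shape != lens.shape:
        raise ValueError("spectral_counts and lengths differ in shape")
    if np.any(lens <= 0):
        raise ValueError("protein lengths must be > 0")
    if np.any(counts < 0):
        raise ValueError("spectral counts must be >= 0")
    weighted = counts / lens
    total = weighted.sum()
    if total == 0:
        raise ValueError("all-zero spectral counts: %NSAF undefined")
    return 100.0 * weighted / total


def nsaf_table(counts: pd.DataFrame, lengths: Mapping[str, float]) -> pd.DataFrame:
    """Per-sample %NSAF for a protein x sample spectral-count table."""
    missing = [p for p in counts.index if p not in lengths]
    if missing:
        raise KeyError(f"no length for proteins: {missing}")
    lens = [lengths[p] for p in counts.index]
    data = {c: nsaf(counts[c].to_numpy(), lens) for c in counts.columns}
    return pd.DataFrame(data, index=counts.index)


def merge_technical_duplicates(
    counts: pd.DataFrame, groups: Mapping[str, str], *, how: str = "mean"
) -> pd.DataFrame:
    """Collapse technical-duplicate columns to one column per sample.

    ``groups`` maps column name to sample name; ``how`` is "mean" (averaged
    spectral counts) or "sum".
    """
    if how not in ("mean", "sum"):
        raise ValueError("how must be 'mean' or 'sum'")
    missing = [c for c in counts.columns if c not in groups]
    if missing:
        raise KeyError(f"columns without a sample group: {missing}")
    grouped = counts.T.groupby([groups[c] for c in counts.columns])
    merged = grouped.mean() if how == "mean" else grouped.sum()
    return merged.T


def link_expression(
    expressed: Sequence[tuple[str, str, str, float]],
    representatives: Sequence[SusCDCluster],
    *,
    min_aa_identity: float = 90.0,
) -> list[tuple[str, str, str, float, float]]:
    """Link expressed proteins to representative SusC/D clusters.

    ``expressed`` holds (protein_id, aa_sequence, sample, %NSAF) tuples. A
    protein links to the representative cluster with the highest global
    amino-acid identity to its centroid, provided it reaches
    ``min_aa_identity``; ties go to the lexicographically first cluster id.
    Returns (protein_id, cluster_id, sample, %NSAF, identity) links.
    """
    reps = [c for c in representatives if c.is_representative]
    links = []
    for protein_id, aa_seq, sample, pct_nsaf in expressed:
        if not aa_seq:
            raise ValueError(f"{protein_id}: empty amino-acid sequence")
        best: tuple[float, str] | None = None
        for c in sorted(reps, key=lambda c: c.cluster_id):
            target = c.centroid.aa_sequence
            if not target:
                continue
            ident = global_identity(aa_seq, target)
            if best is None or ident > best[0]:
                best = (ident, c.cluster_id)
        if best is not None and best[0] >= min_aa_identity:
            links.append((protein_id, best[1], sample, pct_nsaf, best[0]))
    return links
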