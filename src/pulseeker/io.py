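"""Readers and writers for the pipeline's file dialects.

Inputs follow the upstream tools' conventions: HMMER3 ``--domtblout``
tables (whitespace-delimited, '#' comments), BLAST/DIAMOND tabular
``outfmt 6`` (qseqid sseqid pident length mismatch gapopen qstart qend
sstart send evalue bitscore) with a sidecar subject-to-family map, and
FASTA via Biopython. Outputs are plain TSV with a provenance header line
(package version and configuration hash) plus JSON sketches and manifests.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .annotation import DomainHit, GeneRecord, GeneRole, SimilarityHit
from .mashclust import MagQuality, MashCluster, Sketch
from .pulcall import PUL


def _header(config_digest: str | None) -> str:
    tag = f" config={config_digest}" if config_digest else ""
    return f"# pulseeker v{__version__}{tag}\n"


def write_tsv(df: pd.DataFrame, path: str | Path, *, config_digest: str | None = None,
              index: bool = False, index_label: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config_digest))
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def read_tsv(path: str | Path, *, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# -- gene tables -------------------------------------------------------------

def write_gene_table(genes: Sequence[GeneRecord], path: str | Path, **kw) -> None:
    df = pd.DataFrame(
        [
            (g.contig_id, g.gene_index, g.gene_id, g.start, g.end, g.strand, g.aa_length)
            for g in genes
        ],
        columns=["contig_id", "gene_index", "gene_id", "start", "end", "strand", "aa_length"],
    )
    write_tsv(df, path, **kw)


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    df = read_tsv(path)
    return [
        GeneRecord(
            contig_id=str(r.contig_id),
            gene_index=int(r.gene_index),
            gene_id=str(r.gene_id),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            aa_length=int(r.aa_length),
        )
        for r in df.itertuples()
    ]


# -- HMMER domtblout ---------------------------------------------------------

def read_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse a HMMER3 per-domain table (hmmscan orientation: target=model,
    query=protein). Model coordinates come from the hmm columns, query
    coordinates from the ali columns."""
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 22:
                raise ValueError(f"{path}: domtblout line with {len(f)} < 22 columns")
            hits.append(
                DomainHit(
                    gene_id=f[3],
                    model_id=f[0][:-4] if f[0].endswith(".hmm") else f[0],
                    model_length=int(f[2]),
                    ali_from=int(f[15]),
                    ali_to=int(f[16]),
                    i_evalue=float(f[12]),
                    bitscore=float(f[13]),
                    q_from=int(f[17]),
                    q_to=int(f[18]),
                )
            )
    return hits


def write_domtblout(hits: Sequence[DomainHit], gene_lengths: Mapping[str, int],
                    path: str | Path) -> None:
    """Emit hits in the 23-column domtblout dialect the reader accepts."""
    with open(path, "w") as fh:
        fh.write("# synthetic domain hit table (domtblout dialect)\n")
        for i, h in enumerate(hits):
            qlen = gene_lengths[h.gene_id]
            fh.write(
                f"{h.model_id} - {h.model_length} {h.gene_id} - {qlen} "
                f"{h.i_evalue:.2g} {h.bitscore:.1f} 0.0 1 1 {h.i_evalue:.2g} {h.i_evalue:.2g} "
                f"{h.bitscore:.1f} 0.0 {h.ali_from} {h.ali_to} {h.q_from} {h.q_to} "
                f"{h.q_from} {h.q_to} 0.99 -\n"
            )


# -- BLAST/DIAMOND tabular ---------------------------------------------------

def read_blast_tab(
    path: str | Path,
    family_map: Mapping[str, str],
    query_lengths: Mapping[str, int],
) -> list[SimilarityHit]:
    """Parse outfmt-6 rows into family-resolved similarity hits.

    Query coverage is (qend - qstart + 1) / query length; the sidecar
    ``family_map`` resolves subject ids to CAZy families.
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: outfmt-6 line with {len(f)} < 12 columns")
            qseqid, sseqid = f[0], f[1]
            if sseqid not in family_map:
                raise ValueError(f"{path}: subject {sseqid!r} missing from family map")
            if qseqid not in query_lengths:
                raise ValueError(f"{path}: query {qseqid!r} has no known length")
            qcov = (int(f[7]) - int(f[6]) + 1) / query_lengths[qseqid]
            hits.append(
                SimilarityHit(
                    query_gene_id=qseqid,
                    subject_family=family_map[sseqid],
                    pct_identity=float(f[2]),
                    query_coverage=min(1.0, qcov),
                    evalue=float(f[10]),
                )
            )
    return hits


def write_blast_tab(
    hits: Sequence[SimilarityHit],
    query_lengths: Mapping[str, int],
    path: str | Path,
    family_map_path: str | Path | None = None,
) -> None:
    """Emit similarity hits as outfmt-6 rows plus a subject→family sidecar."""
    fam_rows = {}
    with open(path, "w") as fh:
        for i, h in enumerate(hits):
            qlen = query_lengths[h.query_gene_id]
            alen = max(1, round(h.query_coverage * qlen))
            sseqid = f"CAZY|{h.subject_family}|{i:05d}"
            fam_rows[sseqid] = h.subject_family
            mism = max(0, round(alen * (1 - h.pct_identity / 100)))
            fh.write(
                f"{h.query_gene_id}\t{sseqid}\t{h.pct_identity:.1f}\t{alen}\t{mism}\t0\t"
                f"1\t{alen}\t1\t{alen}\t{h.evalue:.2g}\t{alen * 2}\n"
            )
    if family_map_path is not None:
        write_family_map(fam_rows, family_map_path)


def write_family_map(mapping: Mapping[str, str], path: str | Path) -> None:
    df = pd.DataFrame(sorted(mapping.items()), columns=["subject_id", "family"])
    write_tsv(df, path)


def read_family_map(path: str | Path) -> dict[str, str]:
    df = read_tsv(path)
    return dict(zip(df["subject_id"].astype(str), df["family"].astype(str)))


# -- gene roles --------------------------------------------------------------

def write_roles(roles: Sequence[GeneRole], path: str | Path, **kw) -> None:
    df = pd.DataFrame(
        [
            (r.gene_id, ",".join(sorted(r.roles)), ",".join(r.families), r.is_gt_only)
            for r in roles
        ],
        columns=["gene_id", "roles", "families", "is_gt_only"],
    )
    write_tsv(df, path, **kw)


def read_roles(path: str | Path) -> list[GeneRole]:
    df = read_tsv(path)
    out = []
    for r in df.itertuples():
        roles = set(str(r.roles).split(",")) if isinstance(r.roles, str) and r.roles else set()
        fams = str(r.families).split(",") if isinstance(r.families, str) and r.families else []
        out.append(GeneRole(gene_id=str(r.gene_id), roles=roles, families=fams))
    return out


# -- PUL tables --------------------------------------------------------------

def pul_table(puls: Sequence[PUL]) -> pd.DataFrame:
    rows = []
    for i, p in enumerate(puls):
        sub = p.substrate
        rows.append(
            {
                "pul_id": f"pul_{i + 1:04d}",
                "contig_id": p.contig_id,
                "first_index": p.first_index,
                "last_index": p.last_index,
                "n_markers": len(p.marker_genes),
                "n_susCD_pairs": len(p.susCD_pairs),
                "degradative_count": p.degradative_count,
                "families": ",".join(
                    f"{fam}:{n}" for fam, n in sorted(p.feature_counts().items())
                ),
                "touches_contig_edge": p.touches_contig_edge,
                "substrate": sub.label if sub else "",
                "variant": (sub.variant or "") if sub else "",
                "ambiguous": (sub.n_matching_rules > 1) if sub else False,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pul_id", "contig_id", "first_index", "last_index", "n_markers",
            "n_susCD_pairs", "degradative_count", "families",
            "touches_contig_edge", "substrate", "variant", "ambiguous",
        ],
    )


def write_pul_gff3(puls: Sequence[PUL], genes: Sequence[GeneRecord], path: str | Path) -> None:
    """GFF3 features for called loci, for genome-browser inspection."""
    by_key = {(g.contig_id, g.gene_index): g for g in genes}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, p in enumerate(puls):
            first = by_key[(p.contig_id, p.first_index)]
            last = by_key[(p.contig_id, p.last_index)]
            label = p.substrate.label if p.substrate else "unknown"
            fh.write(
                f"{p.contig_id}\tpulseeker\tpolysaccharide_utilization_locus\t"
                f"{first.start}\t{last.end}\t.\t.\t.\t"
                f"ID=pul_{i + 1:04d};substrate={label}\n"
            )


# -- FASTA -------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# -- sketches, distances, clusters ------------------------------------------

def write_sketches(sketches: Sequence[Sketch], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"pulseeker": __version__, "sketches": [s.to_dict() for s in sketches]}, fh)


def read_sketches(path: str | Path) -> list[Sketch]:
    with open(path) as fh:
        data = json.load(fh)
    return [Sketch.from_dict(d) for d in data["sketches"]]


def write_quality_table(qualities: Sequence[MagQuality], path: str | Path, **kw) -> None:
    df = pd.DataFrame(
        [(q.mag_id, q.completeness, q.contamination) for q in qualities],
        columns=["mag_id", "completeness", "contamination"],
    )
    write_tsv(df, path, **kw)


def read_quality_table(path: str | Path) -> dict[str, MagQuality]:
    df = read_tsv(path)
    return {
        str(r.mag_id): MagQuality(str(r.mag_id), float(r.completeness), float(r.contamination))
        for r in df.itertuples()
    }


def cluster_table(clusters: Sequence[MashCluster], qualities: Mapping[str, MagQuality]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        for m in c.member_mag_ids:
            q = qualities[m]
            rows.append(
                {
                    "cluster_id": c.cluster_id,
                    "member": m,
                    "completeness": q.completeness,
                    "contamination": q.contamination,
                    "retained": c.retained,
                    "representative": m in c.representatives,
                    "abundant": c.abundant,
                }
            )
    return pd.DataFrame(rows)
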