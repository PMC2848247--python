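"""File formats. All coordinate conversion happens here: BED and
internal coordinates are 0-based half-open; probe TSV positions and
GFF3 are 1-based inclusive on disk."""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicRegion, sort_regions
from .motif import MotifSite
from .synthetic_types import GeneModel, OrthologPair

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_probe_tsv",
    "write_probe_tsv",
    "read_gene_models",
    "write_gene_models",
    "read_ortholog_pairs",
    "write_ortholog_pairs",
    "sites_to_bed",
    "read_sites_bed",
]


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ------------------------------------------------------------------ BED

def write_bed(path: str | Path, regions: Sequence[GenomicRegion]) -> None:
    with open(path, "w") as fh:
        for r in sort_regions(regions):
            score = "." if r.score is None else f"{r.score:g}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label or '.'}\t{score}\n")


def read_bed(path: str | Path, label: str | None = None) -> list[GenomicRegion]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else ""
            score = (
                float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            )
            out.append(
                GenomicRegion(
                    parts[0], int(parts[1]), int(parts[2]),
                    label if label is not None else name, score,
                )
            )
    return sort_regions(out)


def sites_to_bed(path: str | Path, sites: Sequence[MotifSite]) -> None:
    """BED6: name column carries the strand class (+/-/merged)."""
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda s: (s.chrom, s.start)):
            strand6 = s.strand if s.strand in "+-" else "."
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.strand}\t{s.score:g}\t{strand6}\n"
            )


def read_sites_bed(path: str | Path) -> list[MotifSite]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            out.append(
                MotifSite(p[0], int(p[1]), int(p[2]), p[3], float(p[4]))
            )
    return out


# ---------------------------------------------------------- probe track

def write_probe_tsv(
    path: str | Path, probes: Iterable[tuple[str, int, float]]
) -> None:
    """chrom TAB position TAB signal, positions 1-based on disk."""
    with open(path, "w") as fh:
        for chrom, pos, signal in probes:
            fh.write(f"{chrom}\t{pos + 1}\t{signal:.6g}\n")


def read_probe_tsv(path: str | Path) -> list[tuple[str, int, float]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, signal = line.split("\t")
            out.append((chrom, int(pos) - 1, float(signal)))
    return out


# ------------------------------------------------------------------ GFF3

def write_gene_models(path: str | Path, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.name}"
            if g.score is not None:
                attrs += f";signal={g.score:g}"
            fh.write(
                f"{g.chrom}\tdccmotif\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(g.cds_segments):
                fh.write(
                    f"{g.chrom}\tdccmotif\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                    f"0\tID={g.name}.cds{i};Parent={g.name}\n"
                )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        name = feat.attributes.get("ID", [feat.id])[0]
        score = feat.attributes.get("signal")
        segs = [
            (c.start - 1, c.end)
            for c in db.children(feat, featuretype="CDS", order_by="start")
        ]
        if feat.strand == "-":
            segs = segs[::-1]
        genes.append(
            GeneModel(
                name=name,
                chrom=feat.seqid,
                strand=feat.strand,
                start=feat.start - 1,
                end=feat.end,
                cds_segments=segs,
                score=float(score[0]) if score else None,
            )
        )
    return genes


# ------------------------------------------------------ ortholog pairs

def write_ortholog_pairs(
    path: str | Path, pairs: Sequence[OrthologPair]
) -> None:
    """Aligned FASTA, two records per pair; the query description holds
    the site interval in query coordinates (0-based half-open)."""
    with open(path, "w") as fh:
        for p in pairs:
            flags = []
            if p.truncated_left:
                flags.append("truncated_left")
            if p.truncated_right:
                flags.append("truncated_right")
            extra = (" " + " ".join(flags)) if flags else ""
            fh.write(f">{p.name}/query site={p.site_start}-{p.site_end}{extra}\n")
            fh.write(p.query + "\n")
            fh.write(f">{p.name}/subject\n")
            fh.write(p.subject + "\n")


def read_ortholog_pairs(path: str | Path) -> list[OrthologPair]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2:
        raise ValueError("ortholog pair file must hold records in pairs")
    out = []
    for q, s in zip(records[0::2], records[1::2]):
        name = q.id.rsplit("/", 1)[0]
        if s.id.rsplit("/", 1)[0] != name:
            raise ValueError(f"unpaired records {q.id} / {s.id}")
        site = None
        for token in q.description.split():
            if token.startswith("site="):
                a, b = token[5:].split("-")
                site = (int(a), int(b))
        if site is None:
            raise ValueError(f"record {q.id} lacks a site= interval")
        out.append(
            OrthologPair(
                name=name,
                query=str(q.seq).upper(),
                subject=str(s.seq).upper(),
                site_start=site[0],
                site_end=site[1],
                truncated_left="truncated_left" in q.description,
                truncated_right="truncated_right" in q.description,
            )
        )
    return out
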