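"""File formats.

This is the only module that converts between the package-internal 0-based
half-open intervals and the 1-based inclusive coordinates of GFF3/BED.
Writers emit deterministic, sorted output so that write -> read -> write is
byte-identical.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    GeneModel,
    GenomeAnnotation,
    PeptideLocation,
    RepeatCopy,
    Transcript,
)
from .seqtools import revcomp

GFF_SOURCE = "darkpep"


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write ``(id, sequence)`` pairs; description left empty."""
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# annotation GFF3


def _gff_line(chrom, ftype, start, end, strand, attrs: dict) -> str:
    """One GFF3 line; ``start``/``end`` are internal 0-based half-open."""
    attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
    return f"{chrom}\t{GFF_SOURCE}\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attr_s}"


def write_annotation_gff3(ann: GenomeAnnotation, path) -> None:
    lines = ["##gff-version 3"]
    for gid in sorted(ann.genes):
        g = ann.genes[gid]
        s, e = g.span
        lines.append(_gff_line(g.chrom, "gene", s, e, g.strand, {"ID": gid, "biotype": "protein_coding"}))
        for ftype, ivs in (
            ("exon", g.exons),
            ("CDS", g.cds),
            ("five_prime_UTR", g.utr5),
            ("three_prime_UTR", g.utr3),
            ("intron", g.introns),
        ):
            for s, e in sorted(ivs):
                lines.append(_gff_line(g.chrom, ftype, s, e, g.strand, {"Parent": gid}))
        lines.append(_gff_line(g.chrom, "upstream_flank", *g.upstream, g.strand, {"Parent": gid}))
        lines.append(_gff_line(g.chrom, "downstream_flank", *g.downstream, g.strand, {"Parent": gid}))
    for tid in sorted(ann.transcripts):
        t = ann.transcripts[tid]
        if t.biotype == "protein_coding":
            continue
        attrs = {"ID": tid, "gene_id": t.gene_id, "biotype": t.biotype}
        if t.parent_gene_id:
            attrs["parent_gene"] = t.parent_gene_id
        s, e = t.span
        lines.append(_gff_line(t.chrom, "transcript", s, e, t.strand, attrs))
        for s, e in sorted(t.exons):
            lines.append(_gff_line(t.chrom, "exon", s, e, t.strand, {"Parent": tid}))
    for r in ann.repeats:
        lines.append(
            _gff_line(r.chrom, "repeat_region", r.start, r.end, r.strand, {"ID": r.copy_id, "family": r.family})
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(s: str) -> dict:
    out = {}
    for item in s.strip().split(";"):
        if item:
            k, _, v = item.partition("=")
            out[k] = v
    return out


def read_annotation_gff3(path, genome: dict[str, str]) -> GenomeAnnotation:
    """Rebuild a :class:`GenomeAnnotation` from GFF3; spliced sequences come
    from ``genome``."""
    genes: dict[str, dict] = {}
    ncs: dict[str, dict] = {}
    repeats: list[RepeatCopy] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _src, ftype, start, end, _score, strand, _phase, attr_s = line.split("\t")
        iv = (int(start) - 1, int(end))
        attrs = _parse_attrs(attr_s)
        if ftype == "gene":
            genes[attrs["ID"]] = {
                "chrom": chrom,
                "strand": strand,
                "exon": [],
                "CDS": [],
                "five_prime_UTR": [],
                "three_prime_UTR": [],
                "intron": [],
            }
        elif ftype == "transcript":
            ncs[attrs["ID"]] = {
                "chrom": chrom,
                "strand": strand,
                "gene_id": attrs["gene_id"],
                "biotype": attrs["biotype"],
                "parent_gene": attrs.get("parent_gene"),
                "exons": [],
            }
        elif ftype == "repeat_region":
            repeats.append(RepeatCopy(attrs["family"], attrs["ID"], chrom, iv[0], iv[1], strand))
        elif ftype in ("upstream_flank", "downstream_flank"):
            genes[attrs["Parent"]][ftype] = iv
        elif attrs.get("Parent") in genes:
            genes[attrs["Parent"]][ftype].append(iv)
        elif attrs.get("Parent") in ncs:
            ncs[attrs["Parent"]]["exons"].append(iv)
        else:
            raise ValueError(f"orphan feature line: {line}")

    ann = GenomeAnnotation()
    for gid, d in genes.items():
        minus = d["strand"] == "-"

        def ordered(ivs, _minus=minus):
            return sorted(ivs, reverse=_minus)

        ann.genes[gid] = GeneModel(
            gene_id=gid,
            chrom=d["chrom"],
            strand=d["strand"],
            exons=ordered(d["exon"]),
            cds=ordered(d["CDS"]),
            utr5=ordered(d["five_prime_UTR"]),
            utr3=ordered(d["three_prime_UTR"]),
            introns=ordered(d["intron"]),
            upstream=d["upstream_flank"],
            downstream=d["downstream_flank"],
        )
    for tid, d in ncs.items():
        exons = sorted(d["exons"], reverse=d["strand"] == "-")
        chrom_seq = genome[d["chrom"]]
        seq = "".join(chrom_seq[s:e] for s, e in sorted(exons))
        if d["strand"] == "-":
            seq = revcomp(seq)
        ann.transcripts[tid] = Transcript(
            id=tid,
            gene_id=d["gene_id"],
            biotype=d["biotype"],
            chrom=d["chrom"],
            strand=d["strand"],
            exons=exons,
            spliced_sequence=seq,
            parent_gene_id=d["parent_gene"],
        )
    ann.repeats = sorted(repeats, key=lambda r: (r.chrom, r.start, r.copy_id))
    return ann


# ---------------------------------------------------------------------------
# peptide-placement GFF3 / BED


def write_peptide_gff3(locations: list[PeptideLocation], path) -> None:
    """One feature line per genomic block; blocks of one placement share a
    Parent attribute so junction-spanning peptides stay grouped."""
    lines = ["##gff-version 3"]
    for i, loc in enumerate(locations):
        pid = f"pep{i}"
        for j, (s, e) in enumerate(loc.blocks):
            attrs = {
                "ID": f"{pid}.b{j}",
                "Parent": pid,
                "peptide": loc.peptide,
                "frame": loc.frame,
                "entry": loc.source_entry,
            }
            lines.append(_gff_line(loc.chrom, "peptide", s, e, loc.strand, attrs))
    Path(path).write_text("\n".join(lines) + "\n")


def read_peptide_gff3(path) -> list[PeptideLocation]:
    groups: dict[str, dict] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _src, _ftype, start, end, _score, strand, _phase, attr_s = line.split("\t")
        attrs = _parse_attrs(attr_s)
        pid = attrs["Parent"]
        if pid not in groups:
            groups[pid] = {
                "chrom": chrom,
                "strand": strand,
                "peptide": attrs["peptide"],
                "frame": int(attrs["frame"]),
                "entry": attrs["entry"],
                "blocks": [],
            }
            order.append(pid)
        groups[pid]["blocks"].append((int(start) - 1, int(end)))
    return [
        PeptideLocation(
            peptide=d["peptide"],
            chrom=d["chrom"],
            strand=d["strand"],
            blocks=sorted(d["blocks"]),
            frame=d["frame"],
            source_entry=d["entry"],
        )
        for d in (groups[p] for p in order)
    ]


def write_peptide_bed(locations: list[PeptideLocation], path) -> None:
    """BED12-lite export (one line per placement, blocks as thick blocks)."""
    lines = []
    for loc in locations:
        s, e = loc.span
        sizes = ",".join(str(b[1] - b[0]) for b in loc.blocks)
        starts = ",".join(str(b[0] - s) for b in loc.blocks)
        lines.append(
            f"{loc.chrom}\t{s}\t{e}\t{loc.peptide}\t0\t{loc.strand}\t{s}\t{e}\t0\t{len(loc.blocks)}\t{sizes},\t{starts},"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# TSV helpers (all tables go through pandas with a fixed layout)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def df_bytes(df: pd.DataFrame, index: bool = False) -> bytes:
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=index)
    return buf.getvalue().encode()
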