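"""Search-database construction.

The combined target database holds four entry classes: known proteins,
variant (missense-mutated) proteins, three-frame stop-split translations of
noncoding transcripts (pseudogene / lncRNA / repeat), and reversed-sequence
decoys generated from the full target set.  Every noncoding entry carries a
per-residue genomic coordinate map so that identified peptides can later be
placed on the genome without re-alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import read_fasta, write_fasta, write_tsv
from .model import GenomeAnnotation, MutationSpec, Transcript, TranslatedEntry
from .seqtools import digest_tryptic, three_frame_segments, translate_three_frames  # noqa: F401 (re-export)

log = logging.getLogger(__name__)

DECOY_PREFIX = "decoy_"

#: tryptic peptides outside these length bounds are not indexed
PEPTIDE_MIN_LEN = 7
PEPTIDE_MAX_LEN = 45

DEFAULT_MIN_SEGMENT_LEN = 7


def apply_mutation(protein: str, m: MutationSpec) -> str:
    """Apply one missense substitution; validates the reference residue."""
    if not 1 <= m.position <= len(protein):
        raise ValueError(
            f"{m.protein_id}: position {m.position} out of range for length {len(protein)}"
        )
    if protein[m.position - 1] != m.ref_aa:
        raise ValueError(
            f"{m.protein_id}: expected {m.ref_aa} at position {m.position}, "
            f"found {protein[m.position - 1]}"
        )
    return protein[: m.position - 1] + m.alt_aa + protein[m.position :]


def translate_transcript(tx: Transcript, min_segment_len: int = DEFAULT_MIN_SEGMENT_LEN) -> list[TranslatedEntry]:
    """Three-frame translation of a transcript into mapped database entries."""
    gp = tx.genomic_positions()
    entries = []
    for frame, seg_idx, nt_start, aa in three_frame_segments(tx.spliced_sequence, min_segment_len):
        pos = gp[nt_start : nt_start + 3 * len(aa)].reshape(-1, 3)
        entries.append(
            TranslatedEntry(
                entry_id=f"{tx.id}.f{frame}.s{seg_idx}",
                source_transcript=tx.id,
                frame=frame,
                segment_index=seg_idx,
                protein=aa,
                class_tag="noncoding",
                chrom=tx.chrom,
                strand=tx.strand,
                codon_positions=pos,
                biotype=tx.biotype,
                gene_id=tx.gene_id,
            )
        )
    return entries


def make_decoys(entries: list[TranslatedEntry]) -> list[TranslatedEntry]:
    """Reversed-sequence decoys, one per target, IDs prefixed.

    Palindromic proteins (identical to their reversal) are kept but logged:
    they cannot contribute target/decoy discrimination.
    """
    decoys = []
    n_palindromic = 0
    for e in entries:
        rev = e.protein[::-1]
        if rev == e.protein:
            n_palindromic += 1
            log.warning("palindromic protein %s: decoy equals target", e.entry_id)
        decoys.append(
            TranslatedEntry(
                entry_id=DECOY_PREFIX + e.entry_id,
                source_transcript=e.source_transcript,
                frame=e.frame,
                segment_index=e.segment_index,
                protein=rev,
                class_tag="decoy",
                original_class=e.class_tag,
                biotype=e.biotype,
                gene_id=e.gene_id,
            )
        )
    if n_palindromic:
        log.warning("%d palindromic targets in decoy generation", n_palindromic)
    return decoys


@dataclass
class SearchDatabase:
    """Combined target+decoy database with a class-tagged entry index."""

    entries: dict[str, TranslatedEntry] = field(default_factory=dict)
    min_segment_len: int = DEFAULT_MIN_SEGMENT_LEN

    def add(self, entry: TranslatedEntry) -> None:
        if entry.entry_id in self.entries:
            raise ValueError(f"duplicate entry ID {entry.entry_id}")
        self.entries[entry.entry_id] = entry

    def by_class(self, class_tag: str) -> list[TranslatedEntry]:
        return [e for e in self.entries.values() if e.class_tag == class_tag]

    def targets(self) -> list[TranslatedEntry]:
        return [e for e in self.entries.values() if e.class_tag != "decoy"]

    # -- persistence --------------------------------------------------------

    def fasta_records(self) -> list[tuple[str, str]]:
        recs = []
        for eid in sorted(self.entries):
            e = self.entries[eid]
            header = f"{e.class_tag}|{eid}|{e.source_transcript}|{e.frame}|{e.segment_index}"
            recs.append((header, e.protein))
        return recs

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.fasta_records(), outdir / "db.fasta")
        rows = []
        for eid in sorted(self.entries):
            e = self.entries[eid]
            nt_start = -1
            if e.codon_positions is not None and len(e.codon_positions):
                nt_start = 1  # recomputed on load; flag that a map exists
            rows.append(
                {
                    "entry_id": eid,
                    "class_tag": e.class_tag,
                    "source_transcript": e.source_transcript,
                    "frame": e.frame,
                    "segment_index": e.segment_index,
                    "length": len(e.protein),
                    "biotype": e.biotype or "",
                    "gene_id": e.gene_id or "",
                    "original_class": e.original_class or "",
                    "mapped": int(nt_start > 0),
                }
            )
        write_tsv(pd.DataFrame(rows), outdir / "index.tsv")
        with open(outdir / "params.txt", "w") as fh:
            fh.write(f"min_segment_len\t{self.min_segment_len}\n")

    @classmethod
    def read(cls, outdir, annotation: GenomeAnnotation | None = None) -> "SearchDatabase":
        """Reload a database directory.

        Coordinate maps of noncoding entries are rebuilt from ``annotation``
        (they are derivable, so they are not serialized)."""
        outdir = Path(outdir)
        params = dict(
            line.split("\t") for line in (outdir / "params.txt").read_text().splitlines()
        )
        db = cls(min_segment_len=int(params["min_segment_len"]))
        meta = pd.read_csv(outdir / "index.tsv", sep="\t", dtype=str).set_index("entry_id")
        mapped_by_tx: dict[str, dict[tuple[int, int], TranslatedEntry]] = {}
        if annotation is not None:
            for tx in annotation.noncoding_transcripts():
                for e in translate_transcript(tx, db.min_segment_len):
                    mapped_by_tx.setdefault(tx.id, {})[(e.frame, e.segment_index)] = e
        for header, seq in read_fasta(outdir / "db.fasta"):
            _tag, eid, _src, _frame, _seg = header.split("|")
            m = meta.loc[eid]
            rebuilt = None
            if m["class_tag"] == "noncoding" and m["source_transcript"] in mapped_by_tx:
                rebuilt = mapped_by_tx[m["source_transcript"]].get(
                    (int(m["frame"]), int(m["segment_index"]))
                )
            db.add(
                TranslatedEntry(
                    entry_id=eid,
                    source_transcript=m["source_transcript"],
                    frame=int(m["frame"]),
                    segment_index=int(m["segment_index"]),
                    protein=seq,
                    class_tag=m["class_tag"],
                    chrom=rebuilt.chrom if rebuilt else None,
                    strand=rebuilt.strand if rebuilt else None,
                    codon_positions=rebuilt.codon_positions if rebuilt else None,
                    biotype=(m["biotype"] if isinstance(m["biotype"], str) and m["biotype"] else None),
                    gene_id=(m["gene_id"] if isinstance(m["gene_id"], str) and m["gene_id"] else None),
                    original_class=(
                        m["original_class"]
                        if isinstance(m["original_class"], str) and m["original_class"]
                        else None
                    ),
                )
            )
        return db


def build_search_db(
    known_proteome: list[tuple[str, str]],
    annotation: GenomeAnnotation,
    mutations: list[MutationSpec] | None = None,
    min_segment_len: int = DEFAULT_MIN_SEGMENT_LEN,
) -> SearchDatabase:
    """Assemble the combined target database and its reversed decoys."""
    db = SearchDatabase(min_segment_len=min_segment_len)
    proteins = dict(known_proteome)
    if len(proteins) != len(known_proteome):
        raise ValueError("duplicate protein IDs in known proteome")
    for pid in proteins:
        db.add(
            TranslatedEntry(
                entry_id=pid,
                source_transcript=pid,
                frame=0,
                segment_index=0,
                protein=proteins[pid],
                class_tag="known",
            )
        )
    for i, m in enumerate(mutations or []):
        if m.protein_id not in proteins:
            raise ValueError(f"mutation references unknown protein {m.protein_id}")
        db.add(
            TranslatedEntry(
                entry_id=f"{m.protein_id}.var{i}",
                source_transcript=m.protein_id,
                frame=0,
                segment_index=0,
                protein=apply_mutation(proteins[m.protein_id], m),
                class_tag="variant",
            )
        )
    for tx in annotation.noncoding_transcripts():
        for e in translate_transcript(tx, min_segment_len):
            db.add(e)
    for d in make_decoys(db.targets()):
        db.add(d)
    return db
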