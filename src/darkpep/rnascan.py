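"""Orthogonal RNA-seq evidence for novel peptide regions.

A read supports a peptide placement when its reference span overlaps any
placement block by at least ``min_overlap`` bases and its edit distance
(NM tag) is at most ``max_mismatch``.  Input is SAM text at desk scale;
the record scan is a deliberately minimal text reader so that malformed
records can be skipped (and counted) instead of aborting the run.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .model import PeptideLocation

log = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"^(?:\d+[MIDNSHP=X])+$")
_CIGAR_OP_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")


@dataclass
class AlignmentRecord:
    read_id: str
    chrom: str
    pos: int  # 0-based leftmost reference position
    ref_len: int
    edit_distance: int | None

    @property
    def ref_end(self) -> int:
        return self.pos + self.ref_len


def _reference_length(cigar: str) -> int:
    return sum(int(n) for n, op in _CIGAR_OP_RE.findall(cigar) if op in _REF_CONSUMING)


def iter_sam_records(sam_text_or_path):
    """Yield AlignmentRecord per mapped record; malformed or unmapped
    records are skipped with a warning count (reported at the end)."""
    if isinstance(sam_text_or_path, Path):
        text = sam_text_or_path.read_text()
    else:
        text = str(sam_text_or_path)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
    skipped = 0
    for line in text.splitlines():
        if not line or line.startswith("@"):
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            skipped += 1
            continue
        qname, flag, rname, pos, _mapq, cigar = fields[0], fields[1], fields[2], fields[3], fields[4], fields[5]
        if rname == "*" or cigar == "*":
            skipped += 1
            continue
        if not _CIGAR_RE.match(cigar):
            skipped += 1
            continue
        ref_len = _reference_length(cigar)
        if ref_len < 1:
            skipped += 1
            continue
        nm = None
        for tag in fields[11:]:
            if tag.startswith("NM:i:"):
                nm = int(tag[5:])
                break
        yield AlignmentRecord(
            read_id=qname,
            chrom=rname,
            pos=int(pos) - 1,
            ref_len=ref_len,
            edit_distance=nm,
        )
    if skipped:
        log.warning("skipped %d malformed/unmapped SAM records", skipped)


def count_supporting_reads(
    locations: list[PeptideLocation],
    sam_text_or_path,
    sample_id: str = "sample",
    min_overlap: int = 1,
    max_mismatch: int = 1,
    require_all_blocks: bool = False,
    missing_nm: str = "fail",
) -> pd.DataFrame:
    """Count reads supporting each peptide placement.

    A read counts once per placement.  ``require_all_blocks`` demands the
    min-overlap in every block (off by default: any block suffices, the
    junction case).  Reads lacking an NM tag fail the mismatch filter
    unless ``missing_nm='zero'`` treats the missing tag as 0.
    """
    if missing_nm not in ("fail", "zero"):
        raise ValueError(f"unknown missing_nm policy {missing_nm!r}")
    counts = {loc.placement_id: 0 for loc in locations}
    by_chrom: dict[str, list[PeptideLocation]] = {}
    for loc in locations:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    for rec in iter_sam_records(sam_text_or_path):
        nm = rec.edit_distance
        if nm is None:
            if missing_nm == "fail":
                continue
            nm = 0
        if nm > max_mismatch:
            continue
        for loc in by_chrom.get(rec.chrom, ()):  # desk-scale linear scan
            overlaps = [
                min(rec.ref_end, e) - max(rec.pos, s) for s, e in loc.blocks
            ]
            if require_all_blocks:
                ok = all(o >= min_overlap for o in overlaps)
            else:
                ok = any(o >= min_overlap for o in overlaps)
            if ok:
                counts[loc.placement_id] += 1
    return pd.DataFrame(
        {
            "placement_id": list(counts),
            "sample_id": sample_id,
            "read_count": list(counts.values()),
        }
    )
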