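"""Low-level sequence primitives: translation, digestion, I/L handling.

Coordinates throughout the package are 0-based half-open; conversion to the
1-based inclusive convention of GFF3 happens only in :mod:`darkpep.io`.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_STANDARD = unambiguous_dna_by_id[1]

#: codon -> amino acid, stop codons map to '*'
CODON_TABLE: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TABLE[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon; any codon containing N (or other ambiguity) -> 'X'."""
    return CODON_TABLE.get(codon, "X")


def translate_frame(seq: str, frame: int) -> str:
    """Translate ``seq`` in reading frame 0/1/2, stops rendered as '*'.

    Trailing bases that do not fill a codon are dropped.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    s = seq.upper()
    n = (len(s) - frame) // 3
    return "".join(translate_codon(s[frame + 3 * i : frame + 3 * i + 3]) for i in range(n))


def three_frame_segments(seq: str, min_segment_len: int):
    """Stop-free translation segments of all three forward frames.

    Yields ``(frame, segment_index, nt_start, aa)`` where ``nt_start`` is the
    offset (within ``seq``) of the first base of the segment's first codon and
    ``segment_index`` counts kept segments per frame.  Segments are the
    maximal stop-free runs of the frame translation with length >=
    ``min_segment_len``.
    """
    if min_segment_len < 1:
        raise ValueError("min_segment_len must be >= 1")
    s = seq.upper()
    for frame in range(3):
        aa = translate_frame(s, frame)
        seg_idx = 0
        start = 0  # residue index where current run began
        for part in aa.split("*"):
            if len(part) >= min_segment_len:
                yield frame, seg_idx, frame + 3 * start, part
                seg_idx += 1
            start += len(part) + 1


def translate_three_frames(seq: str, min_segment_len: int) -> list[tuple[int, int, str]]:
    """Three-frame translation split at stop codons.

    Returns ``(frame, segment_index, peptide)`` triples for every stop-free
    segment of length >= ``min_segment_len``.  Empty input yields an empty
    list.  Codons containing N translate to X; X never matches in downstream
    peptide lookups.
    """
    return [(f, i, p) for f, i, _, p in three_frame_segments(seq, min_segment_len)]


def digest_tryptic(protein: str, missed_cleavages: int = 0) -> list[str]:
    """In-silico tryptic digestion.

    Cleaves C-terminal to K or R except when the next residue is P.  Emits
    every peptide spanning at most ``missed_cleavages`` internal cleavage
    sites, ordered by start position then length.
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    if not protein:
        return []
    # indices one past each cleavage point, plus both ends
    cuts = [0]
    for i, aa in enumerate(protein[:-1]):
        if aa in "KR" and protein[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(protein))
    peptides = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + missed_cleavages, len(cuts))):
            peptides.append(protein[cuts[a] : cuts[b]])
    return peptides


def collapse_il(peptide: str) -> str:
    """Map I to L so that mass-indistinguishable sequences compare equal."""
    return peptide.upper().replace("I", "L")


def strip_modifications(peptide: str) -> str:
    """Remove modification annotations, keeping only amino-acid letters."""
    return "".join(c for c in peptide.upper() if c.isalpha())
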