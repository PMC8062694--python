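"""Shared domain containers.

Interval convention: all coordinates held in these objects are 0-based,
half-open ``(start, end)`` tuples on the forward genomic strand; exon lists
are ordered in transcription order (descending genomic position on the minus
strand).  GFF3/BED writers convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .seqtools import revcomp, translate_codon

Interval = tuple[int, int]

NONCODING_BIOTYPES = ("pseudogene", "lncRNA", "repeat")


@dataclass
class Transcript:
    """One transcript (coding or noncoding) with its genomic footprint."""

    id: str
    gene_id: str
    biotype: str  # protein_coding | pseudogene | lncRNA | repeat
    chrom: str
    strand: str  # '+' or '-'
    exons: list[Interval]  # transcription order, 0-based half-open
    spliced_sequence: str
    parent_gene_id: Optional[str] = None  # pseudogene -> parental coding gene

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if sum(e - s for s, e in self.exons) != len(self.spliced_sequence):
            raise ValueError(f"{self.id}: exon lengths do not sum to spliced length")

    @property
    def span(self) -> Interval:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    def genomic_positions(self) -> np.ndarray:
        """Genomic position of each spliced-transcript base, transcription order."""
        chunks = []
        for s, e in self.exons:
            if self.strand == "+":
                chunks.append(np.arange(s, e))
            else:
                chunks.append(np.arange(e - 1, s - 1, -1))
        return np.concatenate(chunks) if chunks else np.empty(0, dtype=int)


def splice(genome: dict[str, str], tx: Transcript) -> str:
    """Extract the spliced transcript sequence from the genome."""
    parts = []
    chrom = genome[tx.chrom]
    for s, e in sorted(tx.exons):
        parts.append(chrom[s:e])
    seq = "".join(parts)
    return revcomp(seq) if tx.strand == "-" else seq


@dataclass
class GeneModel:
    """A protein-coding gene with the annotation layers the classifier needs."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]  # transcription order (incl. UTR portions)
    cds: list[Interval]  # transcription order
    utr5: list[Interval]
    utr3: list[Interval]
    introns: list[Interval]
    upstream: Interval  # 1 kb flank beyond the 5' UTR
    downstream: Interval  # 1 kb flank beyond the 3' UTR

    @property
    def span(self) -> Interval:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    def cds_phase_at(self, pos: int) -> Optional[int]:
        """Annotated codon phase (0/1/2) of genomic position ``pos``, or None."""
        offset = 0
        for s, e in self.cds:
            if s <= pos < e:
                if self.strand == "+":
                    return (offset + (pos - s)) % 3
                return (offset + (e - 1 - pos)) % 3
            offset += e - s
        return None


@dataclass
class RepeatCopy:
    family: str
    copy_id: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class GenomeAnnotation:
    """Gene models plus noncoding transcripts and repeat intervals."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    transcripts: dict[str, Transcript] = field(default_factory=dict)
    repeats: list[RepeatCopy] = field(default_factory=list)

    def noncoding_transcripts(self) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.biotype in NONCODING_BIOTYPES]


@dataclass
class TranslatedEntry:
    """A stop-free protein segment from one frame of a transcript.

    ``codon_positions[i]`` holds the three genomic positions (0-based) of the
    codon encoding residue ``i``; chromosome and strand are constant per
    entry, so the full per-residue coordinate record is
    ``(chrom, strand, codon_positions[i])``.
    """

    entry_id: str
    source_transcript: str
    frame: int
    segment_index: int
    protein: str
    class_tag: str  # known | variant | noncoding | decoy
    chrom: Optional[str] = None
    strand: Optional[str] = None
    codon_positions: Optional[np.ndarray] = None  # shape (len(protein), 3)
    original_class: Optional[str] = None  # for decoys: class of the source target
    biotype: Optional[str] = None
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if "*" in self.protein:
            raise ValueError(f"{self.entry_id}: protein contains a stop symbol")
        if self.codon_positions is not None and len(self.codon_positions) != len(self.protein):
            raise ValueError(f"{self.entry_id}: residue map length != protein length")

    @property
    def residue_map(self):
        if self.codon_positions is None:
            return None
        return [(self.chrom, self.strand, tuple(row)) for row in self.codon_positions]


_COMPLEMENT_ONLY = str.maketrans("ACGTN", "TGCAN")


def retranslate_entry(genome: dict[str, str], entry: TranslatedEntry) -> str:
    """Re-derive an entry's protein from the genome via its residue map.

    Codon positions are stored in transcription order, so on the minus
    strand each base is complemented but the order is kept."""
    chrom = genome[entry.chrom]
    out = []
    for p0, p1, p2 in entry.codon_positions:
        codon = chrom[p0] + chrom[p1] + chrom[p2]
        if entry.strand == "-":
            codon = codon.translate(_COMPLEMENT_ONLY)
        out.append(translate_codon(codon))
    return "".join(out)


@dataclass
class MutationSpec:
    """A missense substitution applied to a known protein."""

    protein_id: str
    position: int  # 1-based residue index
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"{self.protein_id}:{self.position} ref equals alt ({self.ref_aa})")


@dataclass
class PSMRecord:
    spectrum_id: str
    sample_id: str
    dataset_id: str
    peptide: str
    score: float
    is_decoy: bool
    matched_entry: str

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("empty peptide in PSM")
        if not np.isfinite(self.score):
            raise ValueError(f"non-finite score for {self.spectrum_id}")


@dataclass
class PeptideVerdict:
    peptide: str
    peptide_class: str  # known | variant | novel
    best_score: float
    q_value: Optional[float]  # novel class only
    supporting_psm_count: int

    @property
    def accepted(self) -> bool:
        return self.q_value is not None


@dataclass
class PeptideLocation:
    """One genomic placement of a peptide; >1 block iff junction-spanning."""

    peptide: str
    chrom: str
    strand: str
    blocks: list[Interval]  # sorted by genomic position, 0-based half-open
    frame: int
    source_entry: str

    def __post_init__(self) -> None:
        if sum(e - s for s, e in self.blocks) != 3 * len(self.peptide):
            raise ValueError(f"{self.peptide}: block lengths != 3 x peptide length")
        if self.blocks != sorted(self.blocks):
            raise ValueError(f"{self.peptide}: blocks not sorted")

    @property
    def placement_id(self) -> str:
        blocks = ",".join(f"{s}-{e}" for s, e in self.blocks)
        return f"{self.peptide}@{self.chrom}:{self.strand}:{blocks}"

    @property
    def span(self) -> Interval:
        return self.blocks[0][0], self.blocks[-1][1]


#: category precedence, highest first (pseudogene wins over everything)
CATEGORY_PRECEDENCE = (
    "pseudogene",
    "lncRNA",
    "retroelement",
    "utr",
    "exonic_altframe",
    "intron_exon_boundary",
    "intronic",
    "upstream",
    "downstream",
    "intergenic",
)


@dataclass
class NovelLocus:
    locus_id: str
    category: str
    unique_peptides: set[str]
    locations: list[PeptideLocation]
    parent_gene_class: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.unique_peptides:
            raise ValueError(f"{self.locus_id}: locus with no peptides")


@dataclass
class EpitopeScoreConfig:
    """Weights and thresholds for dark-antigen candidate selection."""

    w_cleavage: float = 0.225
    w_tap: float = 0.025
    rank_threshold: float = 0.5  # percent
    background_size: int = 1000
    background_seed: int = 0
    fold_change_min: float = 1.5
    combination: str = "additive"  # additive | normalized_average

    def __post_init__(self) -> None:
        if self.w_cleavage < 0 or self.w_tap < 0:
            raise ValueError("weights must be >= 0")
        if not 0 < self.rank_threshold <= 100:
            raise ValueError("rank_threshold must be in (0, 100]")
        if self.background_size < 1:
            raise ValueError("background_size must be >= 1")


@dataclass
class EpitopeCandidate:
    nine_mer: str
    source_locus: str
    mhc_score: float
    cleavage_score: float
    tap_score: float
    combined_score: float
    percent_rank: float
    locus_fold_change: Optional[float]

    def __post_init__(self) -> None:
        if len(self.nine_mer) != 9:
            raise ValueError(f"{self.nine_mer!r} is not a 9-mer")
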