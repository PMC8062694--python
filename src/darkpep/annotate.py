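"""Genomic placement and origin annotation of accepted novel peptides.

Every placement derivable from a mapped database entry is kept (multi-copy
repeat peptides map to all copies).  Each placement gets exactly one origin
category under a fixed precedence in which pseudogene outranks everything:

    pseudogene > lncRNA > retroelement > utr > exonic_altframe
    > intron_exon_boundary > intronic > upstream > downstream > intergenic

and placements are grouped into novel coding loci: by noncoding gene for
pseudogene/lncRNA, by repeat family for retroelements, by (host coding
gene, category) for the gene-associated categories, and by 10 kb
single-linkage clustering for intergenic placements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .dbbuild import SearchDatabase
from .model import (
    CATEGORY_PRECEDENCE,
    GenomeAnnotation,
    NovelLocus,
    PeptideLocation,
)
from .seqtools import collapse_il

log = logging.getLogger(__name__)

FLANK_DISTANCE = 1000  # max distance from a UTR boundary for upstream/downstream
INTERGENIC_LINKAGE = 10_000


# ---------------------------------------------------------------------------
# peptide -> genomic placements


def _blocks_from_positions(positions) -> list[tuple[int, int]]:
    """Merge sorted genomic positions into maximal contiguous blocks."""
    pos = sorted(int(p) for p in positions)
    blocks = []
    start = prev = pos[0]
    for p in pos[1:]:
        if p == prev + 1:
            prev = p
        else:
            blocks.append((start, prev + 1))
            start = prev = p
    blocks.append((start, prev + 1))
    return blocks


def map_peptide(peptide: str, db: SearchDatabase) -> list[PeptideLocation]:
    """All genomic placements of ``peptide`` over mapped noncoding entries.

    Matching is I/L-insensitive, consistent with the identification stage.
    Returns an empty list (with a warning) if no entry contains the peptide.
    """
    target = collapse_il(peptide)
    found: dict[tuple, PeptideLocation] = {}
    for eid in sorted(db.entries):
        e = db.entries[eid]
        if e.class_tag != "noncoding" or e.codon_positions is None:
            continue
        prot = collapse_il(e.protein)
        start = prot.find(target)
        while start != -1:
            pos = e.codon_positions[start : start + len(target)].ravel()
            blocks = _blocks_from_positions(pos)
            loc = PeptideLocation(
                peptide=peptide,
                chrom=e.chrom,
                strand=e.strand,
                blocks=blocks,
                frame=e.frame,
                source_entry=eid,
            )
            key = (loc.chrom, loc.strand, tuple(loc.blocks), loc.frame)
            found.setdefault(key, loc)
            start = prot.find(target, start + 1)
    if not found:
        log.warning("peptide %s not found in any mapped entry", peptide)
    return list(found.values())


# ---------------------------------------------------------------------------
# category assignment


@dataclass
class AnnotationIndex:
    """Interval-tree indexes over one GenomeAnnotation."""

    ann: GenomeAnnotation
    trees: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        def tree_for(kind):
            return self.trees.setdefault(kind, {})

        def add(kind, chrom, s, e, data):
            if e > s:
                tree_for(kind).setdefault(chrom, IntervalTree()).addi(s, e, data)

        for tx in self.ann.transcripts.values():
            if tx.biotype in ("pseudogene", "lncRNA"):
                s, e = tx.span
                add(tx.biotype, tx.chrom, s, e, tx.gene_id)
        for r in self.ann.repeats:
            add("repeat", r.chrom, r.start, r.end, r.family)
        for g in self.ann.genes.values():
            for s, e in g.utr5 + g.utr3:
                add("utr", g.chrom, s, e, g.gene_id)
            for s, e in g.cds:
                add("cds", g.chrom, s, e, g.gene_id)
            for s, e in g.exons:
                add("exon", g.chrom, s, e, g.gene_id)
            for s, e in g.introns:
                add("intron", g.chrom, s, e, g.gene_id)
            add("upstream", g.chrom, *g.upstream, g.gene_id)
            add("downstream", g.chrom, *g.downstream, g.gene_id)

    def overlapping(self, kind, chrom, blocks):
        """Data payloads of ``kind`` intervals overlapping any block."""
        chrom_tree = self.trees.get(kind, {}).get(chrom)
        if chrom_tree is None:
            return []
        hits = []
        for s, e in blocks:
            hits.extend(iv.data for iv in chrom_tree.overlap(s, e))
        return hits


def _peptide_phase_at(loc: PeptideLocation, pos: int) -> int:
    """Codon phase of the peptide's reading frame at genomic position ``pos``."""
    offset = 0
    for s, e in loc.blocks:
        if s <= pos < e:
            if loc.strand == "+":
                return (offset + (pos - s)) % 3
            break
        offset += e - s
    if loc.strand == "-":
        # coding order runs from the last block backwards
        offset = 0
        for s, e in reversed(loc.blocks):
            if s <= pos < e:
                return (offset + (e - 1 - pos)) % 3
            offset += e - s
    raise ValueError(f"position {pos} outside peptide blocks")


def _altframe_hosts(loc: PeptideLocation, ann: GenomeAnnotation, index: AnnotationIndex):
    """Coding genes whose CDS overlaps the peptide in a different frame."""
    hosts = []
    for gid in set(index.overlapping("cds", loc.chrom, loc.blocks)):
        g = ann.genes[gid]
        if g.strand != loc.strand:
            hosts.append(gid)
            continue
        # find one genomic position where both the peptide and the CDS code
        probe = None
        for cs, ce in g.cds:
            for bs, be in loc.blocks:
                lo, hi = max(cs, bs), min(ce, be)
                if lo < hi:
                    probe = lo
                    break
            if probe is not None:
                break
        if probe is None:
            continue
        if g.cds_phase_at(probe) != _peptide_phase_at(loc, probe):
            hosts.append(gid)
    return hosts


def annotate_location(loc: PeptideLocation, ann: GenomeAnnotation, index: AnnotationIndex | None = None):
    """Assign the origin category and the grouping key of one placement.

    Returns ``(category, key)`` where ``key`` identifies the locus group:
    the noncoding gene, repeat family, or host coding gene.  Intergenic
    placements return ``key=None`` (clustered later).
    """
    if index is None:
        index = AnnotationIndex(ann)
    chrom, blocks = loc.chrom, loc.blocks

    hits = index.overlapping("pseudogene", chrom, blocks)
    if hits:
        return "pseudogene", sorted(hits)[0]
    hits = index.overlapping("lncRNA", chrom, blocks)
    if hits:
        return "lncRNA", sorted(hits)[0]
    hits = index.overlapping("repeat", chrom, blocks)
    if hits:
        return "retroelement", sorted(hits)[0]
    hits = index.overlapping("utr", chrom, blocks)
    if hits:
        return "utr", sorted(hits)[0]
    hosts = _altframe_hosts(loc, ann, index)
    if hosts:
        return "exonic_altframe", sorted(hosts)[0]
    exon_hosts = set(index.overlapping("exon", chrom, blocks))
    intron_hosts = set(index.overlapping("intron", chrom, blocks))
    boundary = exon_hosts & intron_hosts
    if boundary:
        return "intron_exon_boundary", sorted(boundary)[0]
    if intron_hosts:
        return "intronic", sorted(intron_hosts)[0]
    hits = index.overlapping("upstream", chrom, blocks)
    if hits:
        return "upstream", sorted(hits)[0]
    hits = index.overlapping("downstream", chrom, blocks)
    if hits:
        return "downstream", sorted(hits)[0]
    return "intergenic", None


def assign_category(loc: PeptideLocation, ann: GenomeAnnotation, index: AnnotationIndex | None = None) -> str:
    """Origin category of one placement (total: intergenic is the fallback)."""
    category, _key = annotate_location(loc, ann, index)
    return category


# ---------------------------------------------------------------------------
# locus grouping


def group_into_loci(
    placements: list[PeptideLocation],
    ann: GenomeAnnotation,
    index: AnnotationIndex | None = None,
) -> list[NovelLocus]:
    """Partition placements into novel coding loci.

    A peptide whose placements all fall into annotated repeat copies is
    treated as one retroelement locus (grouped by family) rather than being
    discarded for multi-mapping.
    """
    if index is None:
        index = AnnotationIndex(ann)
    annotated = [(loc, *annotate_location(loc, ann, index)) for loc in placements]

    # repeat multi-mapping: collapse a peptide's placements if all are repeat
    by_peptide: dict[str, list] = {}
    for item in annotated:
        by_peptide.setdefault(collapse_il(item[0].peptide), []).append(item)

    groups: dict[tuple, dict] = {}

    def feed(locus_id, category, loc):
        g = groups.setdefault((locus_id, category), {"peptides": set(), "locations": []})
        g["peptides"].add(collapse_il(loc.peptide))
        g["locations"].append(loc)

    intergenic: list[PeptideLocation] = []
    for _pep, items in sorted(by_peptide.items()):
        if all(cat == "retroelement" for _loc, cat, _k in items):
            for loc, _cat, fam in items:
                feed(fam, "retroelement", loc)
            continue
        for loc, cat, key in items:
            if cat in ("pseudogene", "lncRNA"):
                feed(key, cat, loc)
            elif cat == "retroelement":
                feed(key, cat, loc)
            elif cat == "intergenic":
                intergenic.append(loc)
            else:
                feed(f"{key}:{cat}", cat, loc)

    # intergenic: same-strand single-linkage clustering within 10 kb
    keyed = sorted(intergenic, key=lambda l: (l.chrom, l.strand, l.span))
    cluster_n = 0
    i = 0
    while i < len(keyed):
        j = i
        chrom, strand = keyed[i].chrom, keyed[i].strand
        end = keyed[i].span[1]
        members = [keyed[i]]
        while (
            j + 1 < len(keyed)
            and keyed[j + 1].chrom == chrom
            and keyed[j + 1].strand == strand
            and keyed[j + 1].span[0] - end <= INTERGENIC_LINKAGE
        ):
            j += 1
            members.append(keyed[j])
            end = max(end, keyed[j].span[1])
        cluster_n += 1
        lid = f"intergenic:{chrom}:{strand}:{cluster_n}"
        for loc in members:
            feed(lid, "intergenic", loc)
        i = j + 1

    loci = [
        NovelLocus(
            locus_id=lid,
            category=cat,
            unique_peptides=g["peptides"],
            locations=g["locations"],
        )
        for (lid, cat), g in sorted(groups.items())
    ]
    return loci


def filter_min_unique_peptides(loci: list[NovelLocus], k: int = 2) -> list[NovelLocus]:
    """Keep loci supported by at least ``k`` unique peptides (default 2)."""
    return [l for l in loci if len(l.unique_peptides) >= k]


def tag_parent_class(locus: NovelLocus, lookup: dict[str, str]) -> NovelLocus:
    """Attach the parental-gene function class to pseudogene loci."""
    if locus.category == "pseudogene":
        locus.parent_gene_class = lookup.get(locus.locus_id, "unannotated")
    return locus
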