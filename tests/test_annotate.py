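"""Peptide placement, origin-category precedence, locus grouping."""

import numpy as np
import pytest
from oracles import oracle_category

from darkpep.annotate import (
    AnnotationIndex,
    annotate_location,
    assign_category,
    filter_min_unique_peptides,
    group_into_loci,
    map_peptide,
    tag_parent_class,
)
from darkpep.model import (
    CATEGORY_PRECEDENCE,
    GeneModel,
    GenomeAnnotation,
    NovelLocus,
    PeptideLocation,
    RepeatCopy,
    Transcript,
)
from darkpep.seqtools import collapse_il, revcomp, translate_frame


def _ploc(pep, chrom="c1", strand="+", start=0, frame=0, blocks=None, entry="e"):
    blocks = blocks or [(start, start + 3 * len(pep))]
    return PeptideLocation(peptide=pep, chrom=chrom, strand=strand,
                          blocks=blocks, frame=frame, source_entry=entry)


def extract_and_translate(genome, loc):
    """Independent round-trip: splice blocks, strand-orient, translate."""
    seq = "".join(genome[loc.chrom][s:e] for s, e in loc.blocks)
    if loc.strand == "-":
        seq = revcomp(seq)
    return translate_frame(seq, 0)


class TestMapPeptide:
    def test_unique_pseudogene_peptide_roundtrips(self, world, db):
        pg_peps = [
            p for p, lid in world.truth.true_novel_peptides.items() if lid.startswith("PG")
        ]
        tested = 0
        for pep in pg_peps:
            for loc in map_peptide(pep, db):
                assert collapse_il(extract_and_translate(world.genome, loc)) == collapse_il(pep)
                tested += 1
        assert tested > 0

    def test_repeat_peptide_maps_to_every_copy(self, world, db, small_config):
        rep_peps = [
            p for p, lid in world.truth.true_novel_peptides.items() if lid == "L1SYN"
        ]
        # a peptide from the conserved ORF maps to each near-identical copy
        n_copies = small_config.n_repeat_copies
        multi = [p for p in rep_peps if len(map_peptide(p, db)) == n_copies]
        assert multi, "no repeat peptide maps to all copies"

    def test_junction_peptide_has_two_blocks(self, world, db):
        for e in db.by_class("noncoding"):
            tx = world.annotation.transcripts[e.source_transcript]
            if tx.biotype != "lncRNA" or len(tx.exons) < 2:
                continue
            # residue whose codon positions span the exon boundary
            for i in range(len(e.protein) - 5):
                window = e.codon_positions[i : i + 6].ravel()
                if np.abs(np.diff(np.sort(window))).max() > 1:
                    pep = e.protein[i : i + 6]
                    locs = [
                        l for l in map_peptide(pep, db) if l.source_entry == e.entry_id
                    ]
                    assert locs and any(len(l.blocks) == 2 for l in locs)
                    loc = next(l for l in locs if len(l.blocks) == 2)
                    assert sum(b[1] - b[0] for b in loc.blocks) == 3 * len(pep)
                    assert collapse_il(extract_and_translate(world.genome, loc)) == collapse_il(pep)
                    return
        pytest.skip("no junction-spanning lncRNA entry in this world")

    def test_absent_peptide_returns_empty(self, db):
        assert map_peptide("WWWWWWWWWW", db) == []


@pytest.fixture(scope="module")
def toy_annotation():
    """Hand-built annotation: one + strand coding gene, a pseudogene whose
    span overlaps a lncRNA, and one repeat interval."""
    ann = GenomeAnnotation()
    ann.genes["G1"] = GeneModel(
        gene_id="G1", chrom="c1", strand="+",
        exons=[(5000, 5300), (5600, 6000)],
        cds=[(5100, 5300), (5600, 5900)],
        utr5=[(5000, 5100)],
        utr3=[(5900, 6000)],
        introns=[(5300, 5600)],
        upstream=(4000, 5000),
        downstream=(6000, 7000),
    )
    ann.transcripts["PG1.t"] = Transcript(
        id="PG1.t", gene_id="PG1", biotype="pseudogene", chrom="c1", strand="+",
        exons=[(20000, 20300)], spliced_sequence="A" * 300,
    )
    ann.transcripts["LNC1.t"] = Transcript(
        id="LNC1.t", gene_id="LNC1", biotype="lncRNA", chrom="c1", strand="+",
        exons=[(20200, 20500)], spliced_sequence="A" * 300,
    )
    ann.repeats.append(RepeatCopy("R1", "R1.c1", "c1", 30000, 30400, "+"))
    return ann


class TestAssignCategory:
    def test_pseudogene_wins_over_lncrna(self, toy_annotation):
        loc = _ploc("PEPTIDE", start=20250)  # inside both PG1 and LNC1
        cat, key = annotate_location(loc, toy_annotation)
        assert (cat, key) == ("pseudogene", "PG1")

    def test_upstream_within_1kb_of_utr(self, toy_annotation):
        assert assign_category(_ploc("PEPTIDE", start=4500), toy_annotation) == "upstream"

    def test_beyond_1kb_is_intergenic(self, toy_annotation):
        assert assign_category(_ploc("PEPTIDE", start=3400), toy_annotation) == "intergenic"

    def test_exon_intron_boundary(self, toy_annotation):
        # in-frame with the CDS (so not altframe), straddling the 5300 border
        loc = _ploc("PEPTIDE", start=5289)
        assert assign_category(loc, toy_annotation) == "intron_exon_boundary"

    def test_intronic(self, toy_annotation):
        assert assign_category(_ploc("PEPTIDE", start=5400), toy_annotation) == "intronic"

    def test_utr(self, toy_annotation):
        assert assign_category(_ploc("PEPTIDE", start=5050), toy_annotation) == "utr"

    def test_exonic_altframe_requires_frame_shift(self, toy_annotation):
        loc_shift = _ploc("PEPTIDE", start=5152)  # phase 1 vs annotated 0
        assert assign_category(loc_shift, toy_annotation) == "exonic_altframe"
        # same frame as the CDS: not altframe (would have been known)
        loc_same = _ploc("PEPTIDE", start=5151)
        assert assign_category(loc_same, toy_annotation) != "exonic_altframe"

    def test_antisense_cds_overlap_is_altframe(self, toy_annotation):
        loc = _ploc("PEPTIDE", strand="-", start=5150)
        assert assign_category(loc, toy_annotation) == "exonic_altframe"

    def test_retroelement(self, toy_annotation):
        assert assign_category(_ploc("PEPTIDE", start=30100), toy_annotation) == "retroelement"

    def test_downstream(self, toy_annotation):
        assert assign_category(_ploc("PEPTIDE", start=6500), toy_annotation) == "downstream"


class TestCategoryOracle:
    def test_matches_oracle_on_random_locations(self, world):
        rng = np.random.default_rng(17)
        index = AnnotationIndex(world.annotation)
        chroms = sorted(world.genome)
        counts = {}
        for _ in range(2000):
            chrom = chroms[rng.integers(0, len(chroms))]
            n = int(rng.integers(3, 11))
            start = int(rng.integers(0, len(world.genome[chrom]) - 3 * n - 200))
            if rng.random() < 0.2:  # two-block placement
                split = 3 * int(rng.integers(1, n))
                gap = int(rng.integers(50, 150))
                blocks = [(start, start + split), (start + split + gap, start + 3 * n + gap)]
            else:
                blocks = None
            loc = _ploc("A" * n, chrom=chrom, strand="+-"[rng.integers(0, 2)],
                        start=start, blocks=blocks)
            got = assign_category(loc, world.annotation, index)
            want = oracle_category(loc, world.annotation)
            assert got == want, f"{loc.blocks} {loc.strand}: {got} != {want}"
            counts[got] = counts.get(got, 0) + 1
        # the random scan should exercise most categories
        assert len(counts) >= 6

    def test_category_is_total(self, world):
        index = AnnotationIndex(world.annotation)
        loc = _ploc("AAAA", chrom="chr1", start=10)
        assert assign_category(loc, world.annotation, index) in CATEGORY_PRECEDENCE


class TestGroupIntoLoci:
    def test_pseudogene_peptides_group_to_one_locus(self, toy_annotation):
        locs = [_ploc(p, start=20000 + 30 * i) for i, p in enumerate(["AAAAA", "CCCCC", "DDDDD"])]
        loci = group_into_loci(locs, toy_annotation)
        assert len(loci) == 1
        (l,) = loci
        assert l.locus_id == "PG1" and len(l.unique_peptides) == 3

    def test_utr_and_intron_of_same_gene_are_distinct_loci(self, toy_annotation):
        locs = [_ploc("AAAAA", start=5050), _ploc("CCCCC", start=5400),
                _ploc("EEEEE", start=5430)]
        loci = group_into_loci(locs, toy_annotation)
        ids = {l.locus_id for l in loci}
        assert ids == {"G1:utr", "G1:intronic"}

    def test_duplicate_peptide_counts_once(self, toy_annotation):
        locs = [_ploc("AAAAA", start=20010), _ploc("AAAAA", start=20010)]
        (l,) = group_into_loci(locs, toy_annotation)
        assert len(l.unique_peptides) == 1

    def test_intergenic_single_linkage_10kb(self, toy_annotation):
        near = [_ploc("AAAAA", chrom="c2", start=1000), _ploc("CCCCC", chrom="c2", start=6000)]
        far = [_ploc("DDDDD", chrom="c2", start=40000)]
        loci = group_into_loci(near + far, toy_annotation)
        assert len(loci) == 2
        assert all(l.category == "intergenic" for l in loci)

    def test_placement_partition(self, toy_annotation):
        locs = [_ploc("AAAAA", start=20010), _ploc("CCCCC", start=5050),
                _ploc("DDDDD", chrom="c2", start=100)]
        loci = group_into_loci(locs, toy_annotation)
        ids = [l.placement_id for loc_list in (l.locations for l in loci) for l in loc_list]
        assert sorted(ids) == sorted(l.placement_id for l in locs)

    def test_multimapped_repeat_peptide_kept_as_one_family_locus(self, toy_annotation):
        toy_annotation.repeats.append(RepeatCopy("R1", "R1.c2", "c1", 31000, 31400, "+"))
        locs = [_ploc("AAAAA", start=30100), _ploc("AAAAA", start=31100)]
        loci = group_into_loci(locs, toy_annotation)
        assert len(loci) == 1
        (l,) = loci
        assert l.locus_id == "R1" and l.category == "retroelement"
        assert len(l.locations) == 2  # both placements retained


class TestFilterAndTag:
    def _locus(self, n, locus_id="PG1", category="pseudogene"):
        peps = [f"PEP{i}A" for i in range(n)]
        return NovelLocus(locus_id=locus_id, category=category,
                          unique_peptides=set(peps),
                          locations=[_ploc(p, start=100 + 20 * i) for i, p in enumerate(peps)])

    def test_min_unique_peptide_filter(self):
        loci = [self._locus(1, "A"), self._locus(2, "B"), self._locus(3, "C")]
        assert len(filter_min_unique_peptides(loci, 2)) == 2
        assert filter_min_unique_peptides(loci, 1) == loci
        assert filter_min_unique_peptides(loci, 9) == []

    def test_tag_parent_class(self):
        l = tag_parent_class(self._locus(2), {"PG1": "ribosomal protein"})
        assert l.parent_gene_class == "ribosomal protein"
        missing = tag_parent_class(self._locus(2, "PG9"), {})
        assert missing.parent_gene_class == "unannotated"
        lnc = tag_parent_class(self._locus(2, "LNC1", "lncRNA"), {"LNC1": "x"})
        assert lnc.parent_gene_class is None
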