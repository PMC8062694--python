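"""Seeded generators for a toy proteogenomic study.

The generators emulate the statistical structure of a pan-cancer
proteogenomics reanalysis: a small genome with annotated coding genes
(UTRs, introns, 1 kb flanks), pseudogenes that are substitution-diverged
copies of parental coding genes, lncRNAs carrying short ORFs, a multi-copy
LINE-1-like repeat family, search-engine PSM tables whose score
distributions differ between the known and novel classes, tumor/normal
quantification matrices with planted log2 effects and missing values, a
multi-tissue detection panel, and single-end RNA-seq alignments.

All randomness flows from one root seed through named substreams, so every
stage is individually reproducible and the whole world serializes
byte-identically for a fixed config.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dbbuild import SearchDatabase, translate_transcript
from .io import write_annotation_gff3, write_fasta, write_tsv
from .model import GeneModel, GenomeAnnotation, PSMRecord, RepeatCopy, Transcript
from .seqtools import collapse_il, digest_tryptic, revcomp, translate_frame

BASES = np.array(list("ACGT"))
STOPS = ("TAA", "TAG", "TGA")

READ_LEN = 100  # fixed single-end read length for the SAM simulator


class SizingError(ValueError):
    """Requested element counts exceed chromosome capacity."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, named child stream of the root seed."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic world.

    Defaults mirror the shape of the emulated study: a paired 8-pair
    label-free cohort, a 31-tissue panel, and PSM classes whose score
    separation makes class-specific FDR control matter.
    """

    seed: int = 0
    n_coding_genes: int = 40
    n_pseudogenes: int = 12
    n_lncrnas: int = 10
    n_repeat_copies: int = 5
    pseudogene_divergence: float = 0.08  # substitutions per nt
    psm_counts: dict = field(
        default_factory=lambda: {"known": 8000, "novel_true": 700, "novel_false": 600, "decoy": 600}
    )
    score_distributions: dict = field(
        default_factory=lambda: {"known": (4.0, 1.0), "novel_true": (2.5, 1.0), "null": (0.0, 1.0)}
    )
    decoy_noncoding_fraction: float = 0.5
    missingness_rate: float = 0.1
    n_tumor_pairs: int = 8
    n_tissues: int = 31
    quant_noise_sd: float = 0.25
    quant_baseline: tuple = (20.0, 1.5)  # mean, sd of peptide log2 MS1 baseline
    upregulated_effect: float = 1.0  # log2, added per member peptide in tumor
    n_upregulated: int = 11
    n_chromosomes: int = 3
    max_chromosome_len: int = 1_500_000

    def __post_init__(self) -> None:
        for name in ("pseudogene_divergence", "missingness_rate", "decoy_noncoding_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_coding_genes", "n_pseudogenes", "n_lncrnas", "n_repeat_copies",
                     "n_tumor_pairs", "n_tissues"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


PARENT_CLASSES = (
    "ribosomal protein",
    "cytoskeleton",
    "heat shock protein",
    "translation elongation factor",
    "ribonucleoprotein",
    "peptidylprolyl isomerase",
    "metabolic enzyme",
    "other",
)


@dataclass
class GroundTruth:
    true_novel_peptides: dict[str, str] = field(default_factory=dict)  # peptide -> locus
    planted_upregulated_loci: list[tuple[str, float]] = field(default_factory=list)
    planted_tissue_profile: dict[str, set] = field(default_factory=dict)
    psm_truth: dict[str, str] = field(default_factory=dict)  # spectrum -> correct|incorrect
    parent_gene_class: dict[str, str] = field(default_factory=dict)  # pseudogene gene -> class


@dataclass
class SyntheticWorld:
    genome: dict[str, str]
    annotation: GenomeAnnotation
    known_proteome: list[tuple[str, str]]
    truth: GroundTruth
    config: SimulationConfig

    @property
    def noncoding_transcripts(self) -> list[Transcript]:
        return self.annotation.noncoding_transcripts()


# ---------------------------------------------------------------------------
# world generation


def _random_nt(rng, n: int) -> str:
    return "".join(rng.choice(BASES, n))


def _random_cds(rng, n_codons: int) -> str:
    """ATG + non-stop codons + one stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons + 1:
        c = _random_nt(rng, 3)
        if c not in STOPS:
            codons.append(c)
    codons.append(STOPS[rng.integers(0, 3)])
    return "".join(codons)


def _mutate(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _tx_range_to_genomic(t_start, t_end, exons_tx, exons_gen, strand):
    """Map a transcript-coordinate range onto genomic intervals.

    ``exons_tx``: exon intervals in transcript coordinates (transcription
    order); ``exons_gen``: matching genomic intervals.  Returns genomic
    intervals in transcription order.
    """
    out = []
    for (ts, te), (gs, ge) in zip(exons_tx, exons_gen):
        lo, hi = max(t_start, ts), min(t_end, te)
        if lo >= hi:
            continue
        if strand == "+":
            out.append((gs + (lo - ts), gs + (hi - ts)))
        else:
            out.append((ge - (hi - ts), ge - (lo - ts)))
    return out


def _build_coding_gene(rng, gene_id: str):
    """Return (gene_local_seq, builder) where builder(chrom, offset, strand)
    yields the GeneModel plus the spliced transcript pieces."""
    n_codons = int(rng.integers(80, 151))
    cds = _random_cds(rng, n_codons)
    utr5 = _random_nt(rng, int(rng.integers(60, 201)))
    utr3 = _random_nt(rng, int(rng.integers(60, 201)))
    spliced = utr5 + cds + utr3
    n_introns = int(rng.integers(1, 4))
    cut_points = sorted(rng.choice(np.arange(1, len(spliced)), size=n_introns, replace=False).tolist())
    intron_seqs = [_random_nt(rng, int(rng.integers(100, 401))) for _ in range(n_introns)]

    # exon intervals in transcript coordinates
    bounds = [0] + cut_points + [len(spliced)]
    exons_tx = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]

    pieces = []
    for i, (ts, te) in enumerate(exons_tx):
        pieces.append(spliced[ts:te])
        if i < n_introns:
            pieces.append(intron_seqs[i])
    gene_seq = "".join(pieces)

    # gene-local genomic intervals of exons, forward orientation of the pre-mRNA
    exons_local = []
    cursor = 0
    for i, (ts, te) in enumerate(exons_tx):
        exons_local.append((cursor, cursor + (te - ts)))
        cursor += te - ts
        if i < n_introns:
            cursor += len(intron_seqs[i])

    meta = {
        "spliced": spliced,
        "cds": cds,
        "utr5_len": len(utr5),
        "utr3_len": len(utr3),
        "exons_tx": exons_tx,
        "exons_local": exons_local,
        "gene_id": gene_id,
    }
    return gene_seq, meta


def _finalize_gene(meta, chrom: str, offset: int, strand: str, gene_seq_len: int) -> GeneModel:
    L = gene_seq_len
    if strand == "+":
        exons_gen = [(offset + s, offset + e) for s, e in meta["exons_local"]]
    else:
        exons_gen = [(offset + L - e, offset + L - s) for s, e in meta["exons_local"]]
    exons_tx = meta["exons_tx"]
    u5 = meta["utr5_len"]
    cds_end = u5 + len(meta["cds"])
    cds_iv = _tx_range_to_genomic(u5, cds_end, exons_tx, exons_gen, strand)
    utr5_iv = _tx_range_to_genomic(0, u5, exons_tx, exons_gen, strand)
    utr3_iv = _tx_range_to_genomic(cds_end, exons_tx[-1][1], exons_tx, exons_gen, strand)
    sorted_exons = sorted(exons_gen)
    introns = [
        (sorted_exons[i][1], sorted_exons[i + 1][0]) for i in range(len(sorted_exons) - 1)
    ]
    if strand == "-":
        introns = introns[::-1]
    span_s = offset
    span_e = offset + L
    if strand == "+":
        upstream = (span_s - 1000, span_s)
        downstream = (span_e, span_e + 1000)
    else:
        upstream = (span_e, span_e + 1000)
        downstream = (span_s - 1000, span_s)
    return GeneModel(
        gene_id=meta["gene_id"],
        chrom=chrom,
        strand=strand,
        exons=exons_gen,
        cds=cds_iv,
        utr5=utr5_iv,
        utr3=utr3_iv,
        introns=introns,
        upstream=upstream,
        downstream=downstream,
    )


def generate_world(config: SimulationConfig) -> SyntheticWorld:
    """Build the synthetic genome, annotation, proteome and ground truth."""
    rng_layout = substream(config.seed, "layout")
    rng_gene = substream(config.seed, "genes")
    rng_pg = substream(config.seed, "pseudogenes")
    rng_lnc = substream(config.seed, "lncrnas")
    rng_rep = substream(config.seed, "repeats")
    rng_truth = substream(config.seed, "truth")

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_parts: dict[str, list[str]] = {c: [] for c in chrom_names}
    chrom_len: dict[str, int] = {c: 0 for c in chrom_names}
    ann = GenomeAnnotation()

    def place(chrom: str, seq: str) -> int:
        """Append a gap then ``seq``; return the genomic offset of ``seq``."""
        gap = int(rng_layout.integers(2100, 3001))
        chrom_parts[chrom].append(_random_nt(rng_layout, gap))
        offset = chrom_len[chrom] + gap
        chrom_parts[chrom].append(seq)
        chrom_len[chrom] = offset + len(seq)
        if chrom_len[chrom] > config.max_chromosome_len:
            raise SizingError(
                f"{chrom} exceeds max_chromosome_len={config.max_chromosome_len}; "
                "reduce element counts or raise the cap"
            )
        return offset

    def next_chrom(i: int) -> str:
        return chrom_names[i % len(chrom_names)]

    # coding genes ----------------------------------------------------------
    known_proteome: list[tuple[str, str]] = []
    gene_class: dict[str, str] = {}
    slot = 0
    for i in range(config.n_coding_genes):
        gid = f"G{i + 1:03d}"
        gene_seq, meta = _build_coding_gene(rng_gene, gid)
        strand = "+" if rng_gene.random() < 0.5 else "-"
        chrom = next_chrom(slot)
        slot += 1
        offset = place(chrom, gene_seq if strand == "+" else revcomp(gene_seq))
        ann.genes[gid] = _finalize_gene(meta, chrom, offset, strand, len(gene_seq))
        protein = translate_frame(meta["cds"], 0).rstrip("*")
        known_proteome.append((gid, protein))
        gene_class[gid] = PARENT_CLASSES[int(rng_gene.integers(0, len(PARENT_CLASSES)))]
        # keep the spliced transcript for bookkeeping
        ann.transcripts[f"{gid}.t1"] = Transcript(
            id=f"{gid}.t1",
            gene_id=gid,
            biotype="protein_coding",
            chrom=chrom,
            strand=strand,
            exons=ann.genes[gid].exons,
            spliced_sequence=meta["spliced"],
        )

    truth = GroundTruth()

    # pseudogenes: substitution-diverged copies of a parental CDS -----------
    if config.n_pseudogenes > 0 and config.n_coding_genes == 0:
        raise SizingError("pseudogenes require at least one coding gene as parent")
    for i in range(config.n_pseudogenes):
        gid = f"PG{i + 1:03d}"
        parent_id, _ = known_proteome[int(rng_pg.integers(0, len(known_proteome)))]
        parent_meta_cds = None
        for pid, _prot in known_proteome:
            if pid == parent_id:
                parent_meta_cds = ann.transcripts[f"{pid}.t1"]
        # recover parent CDS (without stop codon) from its spliced transcript
        g = ann.genes[parent_id]
        u5 = sum(e - s for s, e in g.utr5)
        cds_len = sum(e - s for s, e in g.cds)
        parent_cds = parent_meta_cds.spliced_sequence[u5 : u5 + cds_len - 3]
        seq = _mutate(rng_pg, parent_cds, config.pseudogene_divergence)
        strand = "+" if rng_pg.random() < 0.5 else "-"
        chrom = next_chrom(slot)
        slot += 1
        offset = place(chrom, seq if strand == "+" else revcomp(seq))
        ann.transcripts[f"{gid}.t1"] = Transcript(
            id=f"{gid}.t1",
            gene_id=gid,
            biotype="pseudogene",
            chrom=chrom,
            strand=strand,
            exons=[(offset, offset + len(seq))],
            spliced_sequence=seq,
            parent_gene_id=parent_id,
        )
        truth.parent_gene_class[gid] = gene_class[parent_id]

    # lncRNAs: random transcripts with at least one planted ORF -------------
    for i in range(config.n_lncrnas):
        gid = f"LNC{i + 1:03d}"
        orf = _random_cds(rng_lnc, int(rng_lnc.integers(80, 161)))[:-3]  # stop-free
        head = _random_nt(rng_lnc, int(rng_lnc.integers(60, 151)))
        tail = _random_nt(rng_lnc, int(rng_lnc.integers(60, 151)))
        head = head[: len(head) - len(head) % 3]  # keep the ORF in frame 0
        seq = head + orf + tail
        strand = "+" if rng_lnc.random() < 0.5 else "-"
        chrom = next_chrom(slot)
        slot += 1
        two_exon = rng_lnc.random() < 0.4
        if two_exon:
            cut = int(rng_lnc.integers(len(head) + 30, len(head) + len(orf) - 30))
            intron = _random_nt(rng_lnc, int(rng_lnc.integers(100, 301)))
            gene_seq = seq[:cut] + intron + seq[cut:]
            exons_local = [(0, cut), (cut + len(intron), len(gene_seq))]
        else:
            gene_seq = seq
            exons_local = [(0, len(seq))]
        L = len(gene_seq)
        offset = place(chrom, gene_seq if strand == "+" else revcomp(gene_seq))
        if strand == "+":
            exons = [(offset + s, offset + e) for s, e in exons_local]
        else:
            exons = [(offset + L - e, offset + L - s) for s, e in exons_local]
        ann.transcripts[f"{gid}.t1"] = Transcript(
            id=f"{gid}.t1",
            gene_id=gid,
            biotype="lncRNA",
            chrom=chrom,
            strand=strand,
            exons=exons,
            spliced_sequence=seq,
        )

    # LINE-1-like repeat family: near-identical genomic copies --------------
    if config.n_repeat_copies > 0:
        orf1 = _random_cds(rng_rep, 120)[:-3]
        source = _random_nt(rng_rep, 120) + orf1 + _random_nt(rng_rep, 120)
        for i in range(config.n_repeat_copies):
            copy_id = f"L1SYN.c{i + 1}"
            seq = _mutate(rng_rep, source, 0.005)
            chrom = next_chrom(slot)
            slot += 1
            offset = place(chrom, seq)
            ann.transcripts[copy_id] = Transcript(
                id=copy_id,
                gene_id="L1SYN",
                biotype="repeat",
                chrom=chrom,
                strand="+",
                exons=[(offset, offset + len(seq))],
                spliced_sequence=seq,
            )
            ann.repeats.append(RepeatCopy("L1SYN", copy_id, chrom, offset, offset + len(seq), "+"))

    # assemble chromosomes (pad the tail so flanks stay in bounds)
    genome = {}
    for c in chrom_names:
        chrom_parts[c].append(_random_nt(rng_layout, 2000))
        genome[c] = "".join(chrom_parts[c])

    world = SyntheticWorld(
        genome=genome,
        annotation=ann,
        known_proteome=known_proteome,
        truth=truth,
        config=config,
    )
    _plant_true_novel_peptides(world, rng_truth)
    return world


def _plant_true_novel_peptides(world: SyntheticWorld, rng, max_per_locus: int = 12) -> None:
    """Pick, per noncoding gene, tryptic peptides of its translated segments
    that do not occur in the known proteome (under I/L equivalence)."""
    known_blob = "*".join(collapse_il(p) for _n, p in world.known_proteome)
    chosen: dict[str, str] = {}
    by_gene: dict[str, list[str]] = {}
    for tx in world.noncoding_transcripts:
        for entry in translate_transcript(tx):
            for pep in digest_tryptic(entry.protein, 0):
                if not 7 <= len(pep) <= 30 or "X" in pep:
                    continue
                if collapse_il(pep) in known_blob:
                    continue
                by_gene.setdefault(tx.gene_id, []).append(pep)
    for gene in sorted(by_gene):
        peps = sorted(set(by_gene[gene]))
        take = min(max_per_locus, len(peps))
        idx = rng.choice(len(peps), size=take, replace=False)
        for i in sorted(idx):
            if peps[i] not in chosen:
                chosen[peps[i]] = gene
    world.truth.true_novel_peptides = chosen


def write_world(world: SyntheticWorld, outdir) -> None:
    """Serialize the world: FASTA genome/proteome, GFF3 annotation, truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(sorted(world.genome.items()), outdir / "genome.fa")
    write_fasta(world.known_proteome, outdir / "known.fa")
    write_annotation_gff3(world.annotation, outdir / "annotation.gff3")
    t = world.truth
    write_tsv(
        pd.DataFrame(
            sorted(t.true_novel_peptides.items()), columns=["peptide", "locus_id"]
        ),
        outdir / "truth_novel_peptides.tsv",
    )
    write_tsv(
        pd.DataFrame(
            sorted(t.parent_gene_class.items()), columns=["gene_id", "parent_class"]
        ),
        outdir / "truth_parent_class.tsv",
    )


# ---------------------------------------------------------------------------
# a tiny fully hand-specified example (used to verify the filter cascade)

_CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def encode_protein(protein: str) -> str:
    """Reverse-translate with one fixed codon per residue (no stops)."""
    return "".join(_CODON_OF[a] for a in protein)


def cascade_example():
    """Deterministic miniature inputs exercising every identification filter.

    Two single-exon pseudogenes carry three plantable novel peptides; the
    PSM table holds known-matching, variant-matching, novel and decoy
    spectra with fixed scores.  Returns a dict with the genome, annotation,
    known proteome, variant mutation, and PSM list.
    """
    k1 = "MAKRPEITIDEKWWGGHHR"
    k2 = "GGGTTTAAAKVVVPPPR"
    pg_a = "TTTWWWDDDKCCCEEEFFFR"  # two tryptic novel peptides
    pg_b = "HHHMMMNNNKGG"  # one tryptic novel peptide
    rng = np.random.default_rng(0)
    filler1 = _random_nt(rng, 400)
    filler2 = _random_nt(rng, 400)
    seq_a, seq_b = encode_protein(pg_a), encode_protein(pg_b)
    genome = {"c1": filler1 + seq_a + filler2 + seq_b + _random_nt(rng, 200)}
    ann = GenomeAnnotation()
    sa = len(filler1)
    sb = sa + len(seq_a) + len(filler2)
    ann.transcripts["PG_A.t"] = Transcript(
        id="PG_A.t", gene_id="PG_A", biotype="pseudogene", chrom="c1", strand="+",
        exons=[(sa, sa + len(seq_a))], spliced_sequence=seq_a,
    )
    ann.transcripts["PG_B.t"] = Transcript(
        id="PG_B.t", gene_id="PG_B", biotype="pseudogene", chrom="c1", strand="+",
        exons=[(sb, sb + len(seq_b))], spliced_sequence=seq_b,
    )

    def psm(sid, pep, score, decoy=False):
        return PSMRecord(spectrum_id=sid, sample_id="S1", dataset_id="D1",
                         peptide=pep, score=score, is_decoy=decoy, matched_entry="e")

    psms = [
        psm("t_known_tryptic", "RPEITIDEK", 9.0),       # tryptic peptide of k1
        psm("t_known_substring", "ITIDEKWW", 8.5),      # internal substring of k1
        psm("t_variant", "RPEATIDEK", 8.0),             # tryptic peptide of the mutant
        psm("d_known", "RPEITIDEK", 7.0, decoy=True),   # decoy hitting a known tryptic
        psm("d_null", "QQQYYYSSSK", 1.0, decoy=True),   # surviving decoy
        psm("t_novel_a1", "TTTWWWDDDK", 10.0),
        psm("t_novel_a2", "CCCEEEFFFR", 9.5),
        psm("t_novel_b1", "HHHMMMNNNK", 8.0),
        psm("t_novel_low", "NNNPPPQQQW", 0.5),          # below the decoy: rejected
    ]
    return {
        "genome": genome,
        "annotation": ann,
        "known_proteome": [("K1", k1), ("K2", k2)],
        "mutation": ("K1", 7, "I", "A"),
        "psms": psms,
        "novel_peptides": {"TTTWWWDDDK": "PG_A", "CCCEEEFFFR": "PG_A", "HHHMMMNNNK": "PG_B"},
    }


# ---------------------------------------------------------------------------
# PSM simulation


def _tryptic_pool(entries, min_len=7, max_len=30):
    pool = []
    for e in entries:
        for pep in digest_tryptic(e.protein, 0):
            if min_len <= len(pep) <= max_len and "X" not in pep:
                pool.append((pep, e.entry_id))
    return pool


def simulate_psms(world: SyntheticWorld, db: SearchDatabase, config: SimulationConfig) -> list[PSMRecord]:
    """Emit target and decoy PSMs with class-conditional Gaussian scores.

    Correct matches (known targets, true novel targets) draw from their
    class distribution; incorrect novel matches and decoys draw from the
    shared null distribution.  Per-spectrum correctness is recorded in
    ``world.truth.psm_truth``.
    """
    if not db.entries:
        raise ValueError("search database is empty")
    from .fdr import KnownIndex  # local import: fdr does not import simulate

    rng = substream(config.seed, "psms")
    counts = config.psm_counts
    dists = config.score_distributions
    index = KnownIndex.from_proteome(world.known_proteome, variants=[
        (e.entry_id, e.protein) for e in db.by_class("variant")
    ])

    known_pool = _tryptic_pool(db.by_class("known"))
    nc_pool = _tryptic_pool(db.by_class("noncoding"))
    true_set = world.truth.true_novel_peptides
    true_pool = []
    nc_by_pep: dict[str, str] = {}
    for pep, eid in nc_pool:
        nc_by_pep.setdefault(pep, eid)
    for pep in sorted(true_set):
        if pep in nc_by_pep:
            true_pool.append((pep, nc_by_pep[pep]))
    false_pool = [
        (pep, eid)
        for pep, eid in nc_pool
        if pep not in true_set and index.classify(pep) == "novel"
    ]
    decoy_nc_pool = _tryptic_pool([e for e in db.by_class("decoy") if e.original_class == "noncoding"])
    decoy_known_pool = _tryptic_pool(
        [e for e in db.by_class("decoy") if e.original_class in ("known", "variant")]
    )

    def draw(pool, n):
        if n and not pool:
            raise ValueError("empty peptide pool for requested PSM class")
        idx = rng.integers(0, len(pool), size=n) if n else []
        return [pool[i] for i in idx]

    def scores(dist_name, n):
        loc, scale = dists[dist_name]
        return rng.normal(loc, scale, size=n)

    records: list[PSMRecord] = []
    truth = world.truth.psm_truth

    def emit(pairs, scr, is_decoy, correct):
        for (pep, eid), s in zip(pairs, scr):
            sid = f"sp{len(records) + 1:06d}"
            records.append(
                PSMRecord(
                    spectrum_id=sid,
                    sample_id=f"S{len(records) % 4 + 1}",
                    dataset_id="DS1",
                    peptide=pep,
                    score=float(s),
                    is_decoy=is_decoy,
                    matched_entry=eid,
                )
            )
            truth[sid] = "correct" if correct else "incorrect"

    n_known = counts.get("known", 0)
    emit(draw(known_pool, n_known), scores("known", n_known), False, True)
    n_true = counts.get("novel_true", 0)
    emit(draw(true_pool, n_true), scores("novel_true", n_true), False, True)
    n_false = counts.get("novel_false", 0)
    emit(draw(false_pool, n_false), scores("null", n_false), False, False)
    n_decoy = counts.get("decoy", 0)
    if n_decoy:
        from_nc = rng.random(n_decoy) < config.decoy_noncoding_fraction
        n_nc = int(from_nc.sum())
        pairs = draw(decoy_nc_pool, n_nc) + draw(decoy_known_pool, n_decoy - n_nc)
        emit(pairs, scores("null", n_decoy), True, False)
    return records


def psms_to_frame(psms: list[PSMRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spectrum_id": [p.spectrum_id for p in psms],
            "sample_id": [p.sample_id for p in psms],
            "dataset_id": [p.dataset_id for p in psms],
            "peptide": [p.peptide for p in psms],
            "score": [p.score for p in psms],
            "is_decoy": [int(p.is_decoy) for p in psms],
            "matched_entry": [p.matched_entry for p in psms],
        }
    )


# ---------------------------------------------------------------------------
# quantification simulation


def make_paired_design(n_pairs: int, dataset_id: str = "CRC", quant_mode: str = "labelfree_ms1") -> pd.DataFrame:
    """Tumor/normal paired design table, one row per sample."""
    rows = []
    for i in range(1, n_pairs + 1):
        rows.append({"sample_id": f"T{i}", "dataset_id": dataset_id, "condition": "tumor",
                     "pair_id": f"P{i}", "tissue": "", "quant_mode": quant_mode})
        rows.append({"sample_id": f"N{i}", "dataset_id": dataset_id, "condition": "normal",
                     "pair_id": f"P{i}", "tissue": "", "quant_mode": quant_mode})
    return pd.DataFrame(rows)


def simulate_quant(
    loci,
    design: pd.DataFrame,
    config: SimulationConfig,
    planted_effects: dict[str, float] | None = None,
):
    """Peptide-level log2 intensities with planted tumor effects, summarized
    to a locus matrix.

    ``loci`` is either a list of :class:`~darkpep.model.NovelLocus` or a
    mapping ``locus_id -> iterable of peptides``.  The planted log2 effect is
    added to every member peptide of an upregulated locus in tumor samples;
    missing values are injected completely at random at the configured rate.
    """
    from .quantify import summarize_labelfree

    if len(design) == 0:
        raise ValueError("design has no samples")
    if hasattr(loci, "items"):
        locus_map = {lid: sorted(set(peps)) for lid, peps in loci.items()}
    else:
        locus_map = {l.locus_id: sorted(l.unique_peptides) for l in loci}
    rng = substream(config.seed, "quant")
    if planted_effects is None:
        ids = sorted(locus_map)
        k = min(config.n_upregulated, len(ids))
        picked = rng.choice(len(ids), size=k, replace=False)
        planted_effects = {ids[i]: config.upregulated_effect for i in sorted(picked)}

    samples = design["sample_id"].tolist()
    is_tumor = (design["condition"] == "tumor").to_numpy()
    pep_rows = []
    pep_index = []
    pep_locus = {}
    mu0, sd0 = config.quant_baseline
    for lid in sorted(locus_map):
        eff = planted_effects.get(lid, 0.0)
        for pep in locus_map[lid]:
            base = rng.normal(mu0, sd0)
            vals = base + rng.normal(0.0, config.quant_noise_sd, size=len(samples))
            vals = vals + np.where(is_tumor, eff, 0.0)
            if config.missingness_rate > 0:
                miss = rng.random(len(samples)) < config.missingness_rate
                vals = np.where(miss, np.nan, vals)
            pep_rows.append(vals)
            key = f"{lid}::{pep}"
            pep_index.append(key)
            pep_locus[key] = lid
    peptide_table = pd.DataFrame(pep_rows, index=pep_index, columns=samples)
    matrix = summarize_labelfree(peptide_table, pep_locus)
    matrix.design = design
    matrix.peptide_table = peptide_table
    matrix.locus_map = pep_locus
    matrix.planted_effects = planted_effects
    return matrix


def simulate_dataset_detection(
    loci_categories: dict[str, str],
    config: SimulationConfig,
    n_datasets: int = 3,
    n_samples: int = 10,
    p_extra_pseudogene: float = 0.3,
    p_extra_other: float = 0.09,
):
    """Detection of loci across datasets and samples.

    Every locus is detected in one home dataset (with a per-locus
    within-dataset detection rate drawn uniformly, exercising all
    recurrence bins); it recurs in each further dataset with probability
    ``p_extra_pseudogene`` for pseudogene loci and ``p_extra_other``
    otherwise — pseudogene translation recurs across cohorts far more often
    than the other origin classes.

    Returns ``(detection, sample_dataset)``: boolean locus x sample frame
    and the sample -> dataset map.
    """
    rng = substream(config.seed, "datasets")
    datasets = [f"DS{i + 1}" for i in range(n_datasets)]
    samples = [f"{d}.s{j + 1}" for d in datasets for j in range(n_samples)]
    sample_dataset = pd.Series({s: s.split(".")[0] for s in samples})
    detection = pd.DataFrame(False, index=sorted(loci_categories), columns=samples)
    for lid in detection.index:
        home = datasets[int(rng.integers(0, n_datasets))]
        p_extra = (
            p_extra_pseudogene if loci_categories[lid] == "pseudogene" else p_extra_other
        )
        for d in datasets:
            if d == home:
                in_ds = True
            else:
                in_ds = rng.random() < p_extra
            if not in_ds:
                continue
            rate = rng.uniform(0.05, 1.0)
            hits = rng.random(n_samples) < rate
            if not hits.any():
                hits[int(rng.integers(0, n_samples))] = True
            cols = [f"{d}.s{j + 1}" for j in range(n_samples)]
            detection.loc[lid, cols] = hits
    return detection, sample_dataset


def simulate_tissue_panel(locus_ids, config: SimulationConfig):
    """Plant ubiquitous / nonspecific / tissue-specific detection profiles.

    Returns ``(detection, expected)``: a boolean locus x tissue frame and the
    planted class per locus.  Profiles are recorded in no particular tissue
    order; the class thresholds are 1 / 2..14 / >=15 detected tissues.
    """
    rng = substream(config.seed, "tissues")
    tissues = [f"tissue{i + 1:02d}" for i in range(config.n_tissues)]
    ids = sorted(locus_ids)
    rng.shuffle(ids)
    n = len(ids)
    n_ubi = max(1, n // 8) if n else 0
    n_spec = max(1, int(0.4 * n)) if n else 0
    detection = pd.DataFrame(False, index=sorted(ids), columns=tissues)
    expected = {}
    profile = {}
    for rank, lid in enumerate(ids):
        if rank < n_ubi:
            k = int(rng.integers(15, config.n_tissues + 1))
            cls = "ubiquitous"
        elif rank < n_ubi + n_spec:
            k = 1
            cls = "tissue_specific"
        else:
            k = int(rng.integers(2, 15))
            cls = "nonspecific"
        cols = rng.choice(config.n_tissues, size=k, replace=False)
        detection.loc[lid, [tissues[c] for c in cols]] = True
        expected[lid] = cls
        profile[lid] = {tissues[c] for c in cols}
    config_truth = pd.Series(expected).reindex(detection.index)
    return detection, config_truth, profile


# ---------------------------------------------------------------------------
# RNA-seq read simulation (SAM text)


def simulate_reads(
    peptide_locations,
    genome: dict[str, str],
    depth: int,
    mismatch_rate: float,
    seed: int,
) -> str:
    """Single-end 100 nt reads overlapping each peptide placement.

    CIGAR is all-match; substitutions are encoded only through the NM tag
    and the read sequence.  ``depth`` reads are emitted per placement, each
    overlapping a uniformly chosen block by at least 1 bp.
    """
    rng = substream(seed, "reads")
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for c in sorted(genome):
        lines.append(f"@SQ\tSN:{c}\tLN:{len(genome[c])}")
    for li, loc in enumerate(peptide_locations):
        chrom_seq = genome[loc.chrom]
        max_start = len(chrom_seq) - READ_LEN
        for j in range(depth):
            bs, be = loc.blocks[int(rng.integers(0, len(loc.blocks)))]
            lo = max(0, bs - READ_LEN + 1)
            hi = min(be - 1, max_start)
            start = int(rng.integers(lo, hi + 1))
            seq = list(chrom_seq[start : start + READ_LEN])
            k = int(rng.binomial(READ_LEN, mismatch_rate))
            if k:
                pos = rng.choice(READ_LEN, size=k, replace=False)
                for p in pos:
                    alts = [b for b in "ACGT" if b != seq[p]]
                    seq[p] = alts[int(rng.integers(0, 3))]
            lines.append(
                "\t".join(
                    [
                        f"r{li}_{j}",
                        "0",
                        loc.chrom,
                        str(start + 1),
                        "60",
                        f"{READ_LEN}M",
                        "*",
                        "0",
                        "0",
                        "".join(seq),
                        "I" * READ_LEN,
                        f"NM:i:{k}",
                    ]
                )
            )
    return "\n".join(lines) + "\n"
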