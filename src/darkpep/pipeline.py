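"""End-to-end orchestration: search DB -> class-specific FDR -> genomic
annotation -> quantification/differential testing -> tissue classes ->
dark-antigen screening -> RNA-seq support, from one root seed.

``run_demo`` generates a synthetic world and runs every stage, writing all
tables plus a run manifest (parameters, per-stage row counts, SHA-256
digests of outputs).  ``run_pipeline`` exposes the same flow behind stage
toggles with dependency checking.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import annotate as ann_mod
from . import epitopes as epi_mod
from . import fdr as fdr_mod
from . import quantify as quant_mod
from . import rnascan as rna_mod
from . import simulate as sim_mod
from .dbbuild import build_search_db
from .io import write_peptide_bed, write_peptide_gff3, write_tsv
from .model import EpitopeScoreConfig, MutationSpec

STAGES = ("simulate", "builddb", "fdr", "annotate", "quant", "epitopes", "rnascan")

_DEPENDS = {
    "builddb": ("simulate",),
    "fdr": ("builddb",),
    "annotate": ("fdr",),
    "quant": ("annotate",),
    "epitopes": ("quant",),
    "rnascan": ("annotate",),
}


class StageDependencyError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "darkpep_run"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    alpha: float = 0.01
    k_min_peptides: int = 2
    ubiquitous_min: int = 15
    n_variant_mutations: int = 5
    read_depth: int = 10
    read_mismatch_rate: float = 0.01
    max_rnascan_placements: int = 20
    epitope: EpitopeScoreConfig = field(default_factory=EpitopeScoreConfig)
    simulation: sim_mod.SimulationConfig | None = None

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = sim_mod.SimulationConfig(seed=self.seed)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _random_mutations(world, n: int) -> list[MutationSpec]:
    rng = sim_mod.substream(world.config.seed, "mutations")
    muts = []
    for _ in range(n):
        pid, prot = world.known_proteome[int(rng.integers(0, len(world.known_proteome)))]
        pos = int(rng.integers(1, len(prot) + 1))
        ref = prot[pos - 1]
        alts = [a for a in "ACDEFGHIKLMNPQRSTVWY" if a != ref]
        muts.append(MutationSpec(pid, pos, ref, alts[int(rng.integers(0, len(alts)))]))
    return muts


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order; halt with a stage-named error on
    failure and a dependency error if a required upstream stage is off."""
    on = {s: bool(config.stages.get(s, False)) for s in STAGES}
    for stage, deps in _DEPENDS.items():
        if on.get(stage) and not all(on.get(d) for d in deps):
            missing = [d for d in deps if not on.get(d)]
            raise StageDependencyError(f"stage {stage!r} requires {missing}")
    return run_demo(config, enabled=on)


def run_demo(config: PipelineConfig | int = 0, enabled: dict | None = None, outdir=None) -> dict:
    """Generate a synthetic world and run the full pipeline on it.

    Accepts a PipelineConfig or a bare seed.  Returns the run manifest.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig(seed=int(config))
    if outdir is not None:
        config.outdir = str(outdir)
    enabled = enabled or {s: True for s in STAGES}
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    scfg = config.simulation
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "alpha": config.alpha,
            "k_min_peptides": config.k_min_peptides,
            "ubiquitous_min": config.ubiquitous_min,
            "epitope": asdict(config.epitope),
            "simulation": {k: v for k, v in asdict(scfg).items()},
        },
        "counts": {},
        "digests": {},
    }
    counts = manifest["counts"]

    def record(path: Path):
        manifest["digests"][path.name] = _sha256(path)

    def fail(stage, exc):
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- simulate ---------------------------------------------------------
    try:
        world = sim_mod.generate_world(scfg)
        sim_mod.write_world(world, out)
        for name in ("genome.fa", "known.fa", "annotation.gff3",
                     "truth_novel_peptides.tsv", "truth_parent_class.tsv"):
            record(out / name)
        counts["true_novel_peptides"] = len(world.truth.true_novel_peptides)
    except Exception as exc:  # noqa: BLE001
        fail("simulate", exc)
    if not enabled.get("builddb"):
        _write_manifest(manifest, out)
        return manifest

    # --- builddb ----------------------------------------------------------
    try:
        mutations = _random_mutations(world, config.n_variant_mutations)
        db = build_search_db(world.known_proteome, world.annotation, mutations)
        db.write(out / "db")
        counts["db_targets"] = len(db.targets())
        counts["db_entries"] = len(db.entries)
        record(out / "db" / "db.fasta")
        record(out / "db" / "index.tsv")
    except Exception as exc:  # noqa: BLE001
        fail("builddb", exc)
    if not enabled.get("fdr"):
        _write_manifest(manifest, out)
        return manifest

    # --- fdr --------------------------------------------------------------
    try:
        psms = sim_mod.simulate_psms(world, db, scfg)
        write_tsv(sim_mod.psms_to_frame(psms), out / "psms.tsv")
        record(out / "psms.tsv")
        index = fdr_mod.KnownIndex.from_proteome(
            world.known_proteome,
            variants=[(e.entry_id, e.protein) for e in db.by_class("variant")],
        )
        novel_t, novel_d, discarded = fdr_mod.prefilter_for_fdr(psms, index)
        verdicts = fdr_mod.class_specific_fdr(novel_t, novel_d, alpha=config.alpha)
        accepted = fdr_mod.accepted_peptides(verdicts, alpha=config.alpha)
        write_tsv(fdr_mod.verdicts_to_frame(verdicts), out / "verdicts.tsv")
        record(out / "verdicts.tsv")
        counts.update(
            psms_total=len(psms),
            novel_target_psms=len(novel_t),
            novel_decoy_psms=len(novel_d),
            discarded_psms=len(discarded),
            novel_peptides_tested=len(verdicts),
            novel_peptides_accepted=len(accepted),
        )
    except Exception as exc:  # noqa: BLE001
        fail("fdr", exc)
    if not enabled.get("annotate"):
        _write_manifest(manifest, out)
        return manifest

    # --- annotate ---------------------------------------------------------
    try:
        aindex = ann_mod.AnnotationIndex(world.annotation)
        placements = []
        for v in accepted:
            placements.extend(ann_mod.map_peptide(v.peptide, db))
        loci = ann_mod.group_into_loci(placements, world.annotation, aindex)
        loci_kept = ann_mod.filter_min_unique_peptides(loci, config.k_min_peptides)
        for l in loci_kept:
            ann_mod.tag_parent_class(l, world.truth.parent_gene_class)
        write_peptide_gff3(placements, out / "peptides.gff3")
        write_peptide_bed(placements, out / "peptides.bed")
        locus_df = pd.DataFrame(
            {
                "locus_id": [l.locus_id for l in loci_kept],
                "category": [l.category for l in loci_kept],
                "n_unique_peptides": [len(l.unique_peptides) for l in loci_kept],
                "parent_gene_class": [l.parent_gene_class or "" for l in loci_kept],
                "peptides": [";".join(sorted(l.unique_peptides)) for l in loci_kept],
            }
        )
        write_tsv(locus_df, out / "loci.tsv")
        for name in ("peptides.gff3", "peptides.bed", "loci.tsv"):
            record(out / name)
        counts.update(
            placements=len(placements),
            loci_all=len(loci),
            loci_min_peptides=len(loci_kept),
        )
    except Exception as exc:  # noqa: BLE001
        fail("annotate", exc)
    if not enabled.get("quant"):
        _write_manifest(manifest, out)
        return manifest

    # --- quant / diff / tissue class --------------------------------------
    try:
        design = sim_mod.make_paired_design(scfg.n_tumor_pairs)
        write_tsv(design, out / "design.tsv")
        # differential testing runs on complete observations; the
        # missingness knob drives the detection/recurrence stage below
        scfg_quant = replace(scfg, missingness_rate=0.0)
        matrix = sim_mod.simulate_quant(loci_kept, design, scfg_quant)
        write_tsv(matrix.values.reset_index(), out / "locus_matrix.tsv")
        diff = quant_mod.test_differential(matrix, design, mode="paired", adjust="BH")
        write_tsv(diff, out / "differential.tsv")
        fc = quant_mod.fold_change(matrix, design)
        write_tsv(fc.reset_index().rename(columns={"index": "locus_id"}), out / "fold_change.tsv")
        detection, expected_cls, profile = sim_mod.simulate_tissue_panel(
            [l.locus_id for l in loci_kept], scfg
        )
        world.truth.planted_tissue_profile = profile
        world.truth.planted_upregulated_loci = sorted(matrix.planted_effects.items())
        tclass = quant_mod.classify_tissue_specificity(detection, config.ubiquitous_min)
        tclass["planted_class"] = expected_cls
        write_tsv(tclass.reset_index(names="locus_id"), out / "tissue_classes.tsv")
        ds_det, sample_ds = sim_mod.simulate_dataset_detection(
            {l.locus_id: l.category for l in loci_kept}, scfg
        )
        recurrence = quant_mod.recurrence_bins(ds_det, sample_ds)
        write_tsv(recurrence, out / "recurrence.tsv")
        detections = {
            lid: set(sample_ds[ds_det.columns[ds_det.loc[lid]]].unique())
            for lid in ds_det.index
        }
        overlap = quant_mod.cross_dataset_overlap(
            detections, {l.locus_id: l.category for l in loci_kept}
        )
        for name in ("design.tsv", "locus_matrix.tsv", "differential.tsv",
                     "fold_change.tsv", "tissue_classes.tsv", "recurrence.tsv"):
            record(out / name)
        sig = diff[(diff["tested"]) & (diff["p_value"] < 0.05) & (diff["effect"] > 0)]
        counts.update(
            quant_loci=len(matrix.values),
            diff_tested=int(diff["tested"].sum()),
            diff_significant_up=len(sig),
            planted_upregulated=len(matrix.planted_effects),
            tissue_class_errors=int((tclass["expression_class"] != tclass["planted_class"]).sum()),
            pseudogene_recurrence_pct=round(100 * overlap["pseudogene_share"], 1),
            non_pseudogene_recurrence_pct=round(100 * overlap["non_pseudogene_share"], 1),
        )
    except Exception as exc:  # noqa: BLE001
        fail("quant", exc)
    if not enabled.get("epitopes"):
        _write_manifest(manifest, out)
        return manifest

    # --- epitopes ---------------------------------------------------------
    try:
        ecfg = config.epitope
        locus_proteins: dict[str, list[str]] = {}
        for l in loci_kept:
            segs = set()
            for eid in sorted(db.entries):
                e = db.entries[eid]
                if e.class_tag != "noncoding" or e.gene_id != l.locus_id:
                    continue
                from .seqtools import collapse_il
                prot = collapse_il(e.protein)
                if any(collapse_il(p) in prot for p in l.unique_peptides):
                    segs.add(e.protein)
            if segs:
                locus_proteins[l.locus_id] = sorted(segs)
        background = epi_mod.Background.build(world.known_proteome, ecfg)
        epis = epi_mod.score_epitopes(
            locus_proteins, background, ecfg, locus_fold_changes=fc.to_dict()
        )
        cands = epi_mod.select_candidates(epis, ecfg)
        write_tsv(epi_mod.candidates_to_frame(cands), out / "dark_antigens.tsv")
        write_tsv(epi_mod.per_locus_summary(epis, ecfg), out / "dark_antigen_loci.tsv")
        record(out / "dark_antigens.tsv")
        record(out / "dark_antigen_loci.tsv")
        counts.update(
            epitope_windows=len(epis),
            dark_antigen_candidates=len(cands),
            dark_antigen_loci=int(epi_mod.per_locus_summary(epis, ecfg)["has_candidate"].sum()),
        )
    except Exception as exc:  # noqa: BLE001
        fail("epitopes", exc)
    if not enabled.get("rnascan"):
        _write_manifest(manifest, out)
        return manifest

    # --- rnascan ----------------------------------------------------------
    try:
        subset = placements[: config.max_rnascan_placements]
        sam = sim_mod.simulate_reads(
            subset, world.genome, config.read_depth, config.read_mismatch_rate, config.seed
        )
        (out / "reads.sam").write_text(sam)
        counts_df = rna_mod.count_supporting_reads(subset, sam, sample_id="demo")
        write_tsv(counts_df, out / "rna_support.tsv")
        record(out / "reads.sam")
        record(out / "rna_support.tsv")
        counts.update(
            rnascan_placements=len(subset),
            rnascan_supported=int((counts_df["read_count"] > 0).sum()),
        )
    except Exception as exc:  # noqa: BLE001
        fail("rnascan", exc)

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
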