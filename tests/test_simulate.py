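"""Synthetic-world generators: determinism, planted structure, simulators."""

import numpy as np
import pytest
from scipy import stats

from darkpep.dbbuild import build_search_db, translate_transcript
from darkpep.model import retranslate_entry
from darkpep.seqtools import collapse_il, digest_tryptic, translate_three_frames
from darkpep.simulate import (
    SimulationConfig,
    SizingError,
    generate_world,
    make_paired_design,
    simulate_psms,
    simulate_quant,
    simulate_reads,
    simulate_tissue_panel,
    write_world,
)


class TestGenerateWorld:
    def test_pseudogene_count_and_parent_links(self):
        cfg = SimulationConfig(seed=1, n_pseudogenes=5)
        w = generate_world(cfg)
        pgs = [t for t in w.noncoding_transcripts if t.biotype == "pseudogene"]
        assert len(pgs) == 5
        known_ids = {pid for pid, _ in w.known_proteome}
        assert all(t.parent_gene_id in known_ids for t in pgs)

    def test_zero_divergence_copies_parent_cds(self):
        cfg = SimulationConfig(seed=2, pseudogene_divergence=0.0)
        w = generate_world(cfg)
        for t in w.noncoding_transcripts:
            if t.biotype != "pseudogene":
                continue
            g = w.annotation.genes[t.parent_gene_id]
            u5 = sum(e - s for s, e in g.utr5)
            cds_len = sum(e - s for s, e in g.cds)
            parent_cds = w.annotation.transcripts[f"{t.parent_gene_id}.t1"].spliced_sequence[
                u5 : u5 + cds_len - 3
            ]
            assert t.spliced_sequence == parent_cds

    def test_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=9)
        write_world(generate_world(cfg), tmp_path / "a")
        write_world(generate_world(SimulationConfig(seed=9)), tmp_path / "b")
        for name in ("genome.fa", "known.fa", "annotation.gff3", "truth_novel_peptides.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_exons_within_chromosome_bounds(self, world):
        for t in world.annotation.transcripts.values():
            n = len(world.genome[t.chrom])
            for s, e in t.exons:
                assert 0 <= s < e <= n

    def test_lncrnas_carry_an_orf(self, world):
        for t in world.noncoding_transcripts:
            if t.biotype != "lncRNA":
                continue
            segs = translate_three_frames(t.spliced_sequence, 8)  # >= 24 nt
            assert segs, f"{t.id} has no ORF >= 24 nt"

    def test_repeat_family_copies_near_identical(self, world, small_config):
        reps = [t for t in world.noncoding_transcripts if t.biotype == "repeat"]
        assert len(reps) == small_config.n_repeat_copies
        ref = reps[0].spliced_sequence
        for t in reps[1:]:
            assert len(t.spliced_sequence) == len(ref)
            ident = sum(a == b for a, b in zip(ref, t.spliced_sequence)) / len(ref)
            assert ident > 0.98

    def test_coding_genes_have_utrs_introns_flanks(self, world):
        for g in world.annotation.genes.values():
            assert g.utr5 and g.utr3 and g.introns
            assert g.upstream[1] - g.upstream[0] == 1000
            assert g.downstream[1] - g.downstream[0] == 1000

    def test_true_novel_peptides_recoverable_and_absent_from_known(self, world):
        known_blob = "*".join(collapse_il(p) for _n, p in world.known_proteome)
        digested = set()
        for tx in world.noncoding_transcripts:
            for e in translate_transcript(tx):
                digested.update(digest_tryptic(e.protein, 0))
        for pep in world.truth.true_novel_peptides:
            assert pep in digested
            assert collapse_il(pep) not in known_blob

    def test_sizing_error(self):
        with pytest.raises(SizingError):
            generate_world(SimulationConfig(seed=0, n_coding_genes=100,
                                            max_chromosome_len=20_000))


class TestSimulatePsms:
    def test_exact_class_counts(self, world, db, small_config):
        from dataclasses import replace

        cfg = replace(small_config, seed=7,
                      psm_counts={"known": 200, "novel_true": 50, "novel_false": 50, "decoy": 250})
        psms = simulate_psms(world, db, cfg)
        assert len(psms) == 550
        assert sum(p.is_decoy for p in psms) == 250

    def test_no_false_novels_means_all_novel_correct(self, world, db, small_config):
        from dataclasses import replace

        cfg = replace(small_config,
                      psm_counts={"known": 0, "novel_true": 40, "novel_false": 0, "decoy": 0})
        psms = simulate_psms(world, db, cfg)
        assert all(world.truth.psm_truth[p.spectrum_id] == "correct" for p in psms)

    def test_known_scores_exceed_novel_by_configured_shift(self, world, db, small_config):
        from dataclasses import replace

        cfg = replace(small_config, seed=3,
                      psm_counts={"known": 1000, "novel_true": 1000, "novel_false": 0, "decoy": 0},
                      score_distributions={"known": (4.0, 1.0), "novel_true": (2.0, 1.0),
                                           "null": (0.0, 1.0)})
        psms = simulate_psms(world, db, cfg)
        known = [p.score for p in psms if not p.matched_entry.split(".")[0].startswith(("PG", "LNC", "L1SYN"))]
        novel = [p.score for p in psms if p.matched_entry.split(".")[0].startswith(("PG", "LNC", "L1SYN"))]
        assert np.mean(known) > np.mean(novel) + 1.0

    def test_empty_database_rejected(self, world, small_config):
        from darkpep.dbbuild import SearchDatabase

        with pytest.raises(ValueError, match="empty"):
            simulate_psms(world, SearchDatabase(), small_config)


class TestSimulateQuant:
    def test_planted_effect_recovered_in_paired_means(self):
        cfg = SimulationConfig(seed=3, quant_noise_sd=0.1, missingness_rate=0.0)
        design = make_paired_design(8)
        loci = {"L": [f"PEP{i}" for i in range(5)], "M": ["Q1", "Q2"]}
        m = simulate_quant(loci, design, cfg, planted_effects={"L": 1.0})
        pt = m.peptide_table
        t_cols = [f"T{i}" for i in range(1, 9)]
        n_cols = [f"N{i}" for i in range(1, 9)]
        member = [k for k in pt.index if k.startswith("L::")]
        diff = (pt.loc[member, t_cols].to_numpy() - pt.loc[member, n_cols].to_numpy()).mean()
        assert 0.8 <= diff <= 1.2
        other = [k for k in pt.index if k.startswith("M::")]
        d0 = (pt.loc[other, t_cols].to_numpy() - pt.loc[other, n_cols].to_numpy()).mean()
        assert abs(d0) < 0.3

    def test_zero_missingness(self):
        cfg = SimulationConfig(seed=4, missingness_rate=0.0)
        m = simulate_quant({"L": ["A", "B"]}, make_paired_design(4), cfg)
        assert not m.peptide_table.isna().any().any()

    def test_missingness_rate_applied(self):
        cfg = SimulationConfig(seed=4, missingness_rate=0.3)
        loci = {f"L{i}": [f"P{i}{j}" for j in range(10)] for i in range(20)}
        m = simulate_quant(loci, make_paired_design(8), cfg)
        frac = float(m.peptide_table.isna().to_numpy().mean())
        assert 0.25 < frac < 0.35

    def test_empty_design_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="no samples"):
            simulate_quant({"L": ["A"]}, pd.DataFrame(columns=["sample_id"]), SimulationConfig())

    def test_null_pvalues_uniform(self):
        """With no planted effects, paired t p-values are U(0,1)."""
        from darkpep.quantify import test_differential

        cfg = SimulationConfig(seed=11, missingness_rate=0.0)
        loci = {f"L{i:03d}": [f"P{i}a", f"P{i}b", f"P{i}c"] for i in range(500)}
        design = make_paired_design(8)
        m = simulate_quant(loci, design, cfg, planted_effects={})
        res = test_differential(m, design, mode="paired", adjust="none")
        ks = stats.kstest(res["p_value"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01


class TestSimulateReads:
    def _loc(self, world):
        from darkpep.annotate import map_peptide

        db = build_search_db(world.known_proteome, world.annotation)
        for pep in sorted(world.truth.true_novel_peptides):
            locs = map_peptide(pep, db)
            if len(locs) == 1:
                return locs[0]
        raise RuntimeError("no uniquely mapping peptide")

    def test_exact_depth_zero_mismatch(self, world):
        loc = self._loc(world)
        sam = simulate_reads([loc], world.genome, depth=10, mismatch_rate=0.0, seed=5)
        records = [l for l in sam.splitlines() if not l.startswith("@")]
        assert len(records) == 10
        assert all(l.endswith("NM:i:0") for l in records)

    def test_zero_depth_header_only(self, world):
        loc = self._loc(world)
        sam = simulate_reads([loc], world.genome, depth=0, mismatch_rate=0.0, seed=5)
        assert all(l.startswith("@") for l in sam.splitlines())

    def test_mismatch_fraction_matches_binomial_expectation(self, world):
        loc = self._loc(world)
        rate = 0.005
        sam = simulate_reads([loc], world.genome, depth=2000, mismatch_rate=rate, seed=11)
        nm = [int(l.rsplit("NM:i:", 1)[1]) for l in sam.splitlines() if not l.startswith("@")]
        frac = np.mean([x >= 1 for x in nm])
        expected = 1 - (1 - rate) ** 100
        assert abs(frac - expected) <= 0.03

    def test_read_sequences_match_reference_when_exact(self, world):
        loc = self._loc(world)
        sam = simulate_reads([loc], world.genome, depth=5, mismatch_rate=0.0, seed=5)
        for line in sam.splitlines():
            if line.startswith("@"):
                continue
            f = line.split("\t")
            chrom, pos, seq = f[2], int(f[3]) - 1, f[9]
            assert world.genome[chrom][pos : pos + 100] == seq


def test_tissue_panel_profiles_match_classes(small_config):
    detection, expected, profile = simulate_tissue_panel(
        [f"L{i}" for i in range(40)], small_config
    )
    n = detection.sum(axis=1)
    for lid in detection.index:
        k = n[lid]
        cls = expected[lid]
        assert len(profile[lid]) == k
        if cls == "ubiquitous":
            assert k >= 15
        elif cls == "nonspecific":
            assert 2 <= k <= 14
        else:
            assert k == 1
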