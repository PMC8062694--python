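"""Locus summarization, differential testing, tissue classes, recurrence."""

import numpy as np
import pandas as pd
import pytest

from darkpep.quantify import (
    LocusQuantMatrix,
    classify_tissue_specificity,
    cross_dataset_overlap,
    fold_change,
    recurrence_bins,
    summarize_isobaric,
    summarize_labelfree,
    test_differential,
)
from darkpep.simulate import SimulationConfig, make_paired_design, simulate_quant


class TestSummarizeLabelfree:
    def test_sum_of_member_peptides(self):
        pt = pd.DataFrame({"s1": [20.0, 21.0]}, index=["a", "b"])
        m = summarize_labelfree(pt, {"a": "L", "b": "L"})
        assert m.values.loc["L", "s1"] == 41.0
        assert m.provenance == "summed_log2_ms1"

    def test_all_members_missing_gives_missing(self):
        pt = pd.DataFrame({"s1": [np.nan, np.nan], "s2": [1.0, np.nan]}, index=["a", "b"])
        m = summarize_labelfree(pt, {"a": "L", "b": "L"})
        assert np.isnan(m.values.loc["L", "s1"]) and m.values.loc["L", "s2"] == 1.0

    def test_partial_missing_sums_remaining(self):
        pt = pd.DataFrame({"s1": [10.0, np.nan, 12.0]}, index=["a", "b", "c"])
        m = summarize_labelfree(pt, dict.fromkeys("abc", "L"))
        assert m.values.loc["L", "s1"] == 22.0

    def test_unmapped_peptide_rejected(self):
        pt = pd.DataFrame({"s1": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="without locus"):
            summarize_labelfree(pt, {})


class TestSummarizeIsobaric:
    def test_median_log2_ratio(self):
        rv = pd.DataFrame(
            {"ref": [2.0, 2.0, 2.0], "c1": [1.0, 2.0, 4.0]}, index=["a", "b", "c"]
        )  # linear ratios 0.5, 1, 2 -> log2 -1, 0, 1 -> median 0
        m = summarize_isobaric(rv, "ref", dict.fromkeys("abc", "L"))
        assert m.values.loc["L", "c1"] == 0.0
        assert m.provenance == "median_log2_ratio"

    def test_single_peptide_is_own_ratio(self):
        rv = pd.DataFrame({"ref": [2.0], "c1": [8.0]}, index=["a"])
        m = summarize_isobaric(rv, "ref", {"a": "L"})
        assert m.values.loc["L", "c1"] == 2.0

    def test_zero_reference_excluded_with_warning(self, caplog):
        rv = pd.DataFrame({"ref": [0.0, 2.0], "c1": [4.0, 4.0]}, index=["a", "b"])
        import logging

        with caplog.at_level(logging.WARNING):
            m = summarize_isobaric(rv, "ref", {"a": "L", "b": "L"})
        assert "excluding 1" in caplog.text
        assert m.values.loc["L", "c1"] == 1.0  # only peptide b contributes


def _matrix(data, samples):
    return LocusQuantMatrix(values=pd.DataFrame(data, columns=samples).T.T,
                            provenance="summed_log2_ms1")


class TestDifferential:
    design = make_paired_design(4)

    def test_constant_nonzero_difference_degenerate(self):
        vals = {f"T{i}": [2.0] for i in range(1, 5)} | {f"N{i}": [1.0] for i in range(1, 5)}
        res = test_differential(_matrix(vals, list(vals)), self.design, "paired")
        row = res.iloc[0]
        assert row["degenerate"] and row["p_value"] > 0 and row["p_value"] < 1e-300
        assert row["effect"] == 1.0

    def test_identical_groups_p_one(self):
        vals = {f"T{i}": [3.0] for i in range(1, 5)} | {f"N{i}": [3.0] for i in range(1, 5)}
        res = test_differential(_matrix(vals, list(vals)), self.design, "paired")
        assert res.iloc[0]["effect"] == 0.0 and res.iloc[0]["p_value"] == 1.0

    def test_insufficient_pairs_untested(self):
        vals = {"T1": [2.0], "N1": [1.0], "T2": [np.nan], "N2": [1.0],
                "T3": [np.nan], "N3": [1.0], "T4": [np.nan], "N4": [1.0]}
        res = test_differential(_matrix(vals, list(vals)), self.design, "paired")
        assert not res.iloc[0]["tested"]

    def test_bh_adjustment_monotone_and_geq_p(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.normal(0, 1, (30, 8)),
                            index=[f"L{i}" for i in range(30)],
                            columns=self.design["sample_id"])
        m = LocusQuantMatrix(values=vals, provenance="summed_log2_ms1")
        res = test_differential(m, self.design, "paired", adjust="BH")
        ok = res["tested"]
        assert (res.loc[ok, "adjusted_p"] >= res.loc[ok, "p_value"] - 1e-12).all()

    def test_unpaired_mode(self):
        rng = np.random.default_rng(1)
        design = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(10)],
             "condition": ["tumor"] * 5 + ["normal"] * 5}
        )
        vals = pd.DataFrame(
            np.concatenate([rng.normal(3, 0.2, (1, 5)), rng.normal(1, 0.2, (1, 5))], axis=1),
            index=["L"], columns=design["sample_id"],
        )
        res = test_differential(
            LocusQuantMatrix(values=vals, provenance="median_log2_ratio"),
            design, "unpaired", adjust="none",
        )
        assert res.iloc[0]["p_value"] < 1e-4 and res.iloc[0]["effect"] > 1.5

    def test_paired_power_with_planted_effect(self):
        """Planted d = 4 (1 log2 vs sd 0.25) is detected in >= 90% of runs."""
        hits = 0
        n_runs = 100
        design = make_paired_design(8)
        for seed in range(n_runs):
            cfg = SimulationConfig(seed=seed, quant_noise_sd=0.25, missingness_rate=0.0)
            m = simulate_quant({"L": ["p1"]}, design, cfg, planted_effects={"L": 1.0})
            res = test_differential(m, design, "paired", adjust="none")
            hits += res.iloc[0]["p_value"] < 0.05
        assert hits >= 0.9 * n_runs


class TestFoldChange:
    design = make_paired_design(2)

    def _fc(self, tumor, normal):
        vals = {"T1": [tumor], "T2": [tumor], "N1": [normal], "N2": [normal]}
        return fold_change(_matrix(vals, list(vals)), self.design).iloc[0]

    def test_one_log2_is_twofold(self):
        assert self._fc(11.0, 10.0) == pytest.approx(2.0)

    def test_identical_is_one(self):
        assert self._fc(10.0, 10.0) == pytest.approx(1.0)

    def test_minus_one_log2_is_half(self):
        assert self._fc(9.0, 10.0) == pytest.approx(0.5)


class TestTissueClasses:
    def _detect(self, n_detected, n_tissues=31):
        row = [i < n_detected for i in range(n_tissues)]
        return pd.DataFrame([row], index=["L"],
                            columns=[f"t{i}" for i in range(n_tissues)])

    @pytest.mark.parametrize("n,expected", [
        (20, "ubiquitous"),   # at least 15 tissues
        (15, "ubiquitous"),
        (5, "nonspecific"),   # 2-14 tissues
        (14, "nonspecific"),
        (1, "tissue_specific"),
        (0, "undetected"),
    ])
    def test_thresholds(self, n, expected):
        res = classify_tissue_specificity(self._detect(n))
        assert res.loc["L", "expression_class"] == expected
        assert res.loc["L", "n_tissues_detected"] == n

    def test_every_detected_locus_gets_one_class(self):
        rng = np.random.default_rng(2)
        det = pd.DataFrame(rng.random((50, 31)) < 0.3,
                           index=[f"L{i}" for i in range(50)],
                           columns=[f"t{i}" for i in range(31)])
        res = classify_tissue_specificity(det)
        detected = res["n_tissues_detected"] > 0
        assert set(res.loc[detected, "expression_class"]) <= {
            "ubiquitous", "nonspecific", "tissue_specific"
        }


class TestRecurrence:
    def _bins(self, present_of_10):
        det = pd.DataFrame(
            [[i < present_of_10 for i in range(10)]], index=["L"],
            columns=[f"s{i}" for i in range(10)],
        )
        ds = pd.Series("DS1", index=det.columns)
        return recurrence_bins(det, ds).iloc[0]["bin"]

    @pytest.mark.parametrize("present,expected", [
        (10, "0-25"),   # 0 missing
        (9, "0-25"),
        (1, "75-100"),  # 0.9 missing
        (5, "50-75"),   # 0.5 missing falls in the half-open [.5,.75)
        (0, "75-100"),
    ])
    def test_bin_boundaries(self, present, expected):
        assert self._bins(present) == expected

    def test_per_dataset_binning(self):
        det = pd.DataFrame(
            [[True] * 4 + [False] * 4], index=["L"],
            columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
        )
        ds = pd.Series(["D1"] * 4 + ["D2"] * 4, index=det.columns)
        res = recurrence_bins(det, ds).set_index("dataset_id")
        assert res.loc["D1", "bin"] == "0-25" and res.loc["D2", "bin"] == "75-100"


class TestCrossDatasetOverlap:
    def test_locus_in_three_datasets_counts_as_repeat(self):
        res = cross_dataset_overlap({"L": {"a", "b", "c"}}, {"L": "pseudogene"})
        assert res["pseudogene_share"] == 1.0

    def test_all_single_dataset_share_zero(self):
        res = cross_dataset_overlap(
            {f"L{i}": {"a"} for i in range(5)}, {f"L{i}": "lncRNA" for i in range(5)}
        )
        assert res["non_pseudogene_share"] == 0.0

    def test_planted_forty_percent(self):
        det = {f"P{i}": ({"a", "b"} if i < 4 else {"a"}) for i in range(10)}
        res = cross_dataset_overlap(det, {f"P{i}": "pseudogene" for i in range(10)})
        assert res["pseudogene_share"] == pytest.approx(0.4)
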