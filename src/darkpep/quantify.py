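"""Locus-level quantification, differential testing, tissue specificity.

Label-free (MS1) design: the log2 MS1 intensities of a locus's member
peptides are summed per sample; a paired t test compares matched
tumor/normal samples.  Isobaric design: peptide log2 ratios against the
internal reference channel are summarized per locus by the median; an
unpaired two-sided (Welch) t test compares groups.  Missing values are
never imputed; every test uses complete observations only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

RECURRENCE_BINS = ("0-25", "25-50", "50-75", "75-100")  # % of samples missing


@dataclass
class LocusQuantMatrix:
    """Locus x sample log2 matrix; NaN marks missing."""

    values: pd.DataFrame
    provenance: str  # summed_log2_ms1 | median_log2_ratio
    design: Optional[pd.DataFrame] = None
    peptide_table: Optional[pd.DataFrame] = None
    locus_map: Optional[dict] = None
    planted_effects: Optional[dict] = field(default=None, repr=False)


def validate_design(design: pd.DataFrame) -> None:
    required = {"sample_id", "condition"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table lacks columns: {sorted(missing)}")
    bad = set(design["condition"]) - {"tumor", "normal"}
    if bad:
        raise ValueError(f"unknown conditions: {sorted(bad)}")


def summarize_labelfree(peptide_log2: pd.DataFrame, locus_map: dict[str, str]) -> LocusQuantMatrix:
    """Sum member-peptide log2 MS1 intensities per locus and sample.

    A locus value is missing only when every member peptide is missing in
    that sample; otherwise the non-missing members are summed.
    """
    loci = peptide_log2.index.map(locus_map)
    if loci.isna().any():
        orphans = peptide_log2.index[loci.isna()].tolist()
        raise ValueError(f"peptides without locus assignment: {orphans[:5]}")
    values = peptide_log2.groupby(loci.values).sum(min_count=1)
    values.index.name = "locus_id"
    return LocusQuantMatrix(values=values, provenance="summed_log2_ms1",
                            peptide_table=peptide_log2, locus_map=dict(locus_map))


def summarize_isobaric(
    reporter_values: pd.DataFrame,
    reference_channel: str,
    locus_map: dict[str, str],
) -> LocusQuantMatrix:
    """Median per-locus log2 reporter ratio against the internal reference.

    ``reporter_values`` holds linear-scale reporter intensities (peptides x
    channels).  Peptides with a missing or non-positive reference value are
    excluded with a warning.
    """
    ref = reporter_values[reference_channel]
    usable = ref.notna() & (ref > 0)
    if (~usable).any():
        log.warning("excluding %d peptides with missing/zero reference", int((~usable).sum()))
    vals = reporter_values.loc[usable].drop(columns=[reference_channel])
    vals = vals.where(vals > 0)  # non-positive reporter -> missing
    ratios = np.log2(vals.div(ref[usable], axis=0))
    loci = ratios.index.map(locus_map)
    values = ratios.groupby(loci.values).median()
    values.index.name = "locus_id"
    return LocusQuantMatrix(values=values, provenance="median_log2_ratio",
                            peptide_table=ratios, locus_map=dict(locus_map))


_P_FLOOR = float(np.nextafter(0, 1))


def test_differential(
    matrix: LocusQuantMatrix,
    design: pd.DataFrame,
    mode: str = "paired",
    adjust: str = "BH",
) -> pd.DataFrame:
    """Two-sided t tests of tumor vs normal per locus.

    ``mode='paired'`` uses matched pairs (requires ``pair_id``; >= 2
    complete pairs per locus); ``mode='unpaired'`` uses a Welch t test
    (>= 2 non-missing samples per group).  Loci failing the requirement are
    reported with ``tested=False``.  Zero-variance nonzero differences are
    degenerate: the p-value is floored at the smallest positive float and
    flagged.
    """
    validate_design(design)
    if mode not in ("paired", "unpaired"):
        raise ValueError(f"unknown mode {mode!r}")
    if adjust not in ("none", "BH"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    vals = matrix.values
    rows = []
    if mode == "paired":
        if "pair_id" not in design.columns:
            raise ValueError("paired mode requires a pair_id column")
        pairs = []
        for pid, grp in design.groupby("pair_id"):
            t = grp.loc[grp["condition"] == "tumor", "sample_id"]
            n = grp.loc[grp["condition"] == "normal", "sample_id"]
            if len(t) != 1 or len(n) != 1:
                raise ValueError(f"pair {pid} lacks one tumor and one normal sample")
            pairs.append((t.iloc[0], n.iloc[0]))
    for locus, row in vals.iterrows():
        if mode == "paired":
            diffs = np.array([
                row[t] - row[n]
                for t, n in pairs
                if pd.notna(row.get(t)) and pd.notna(row.get(n))
            ])
            n_used = len(diffs)
            if n_used < 2:
                rows.append((locus, np.nan, np.nan, "paired_t", n_used, False, False))
                continue
            effect = float(diffs.mean())
            if np.allclose(diffs.std(ddof=1), 0.0):
                p = 1.0 if np.allclose(effect, 0.0) else _P_FLOOR
                rows.append((locus, effect, p, "paired_t", n_used, True, True))
                continue
            p = float(stats.ttest_1samp(diffs, 0.0).pvalue)
            rows.append((locus, effect, p, "paired_t", n_used, True, False))
        else:
            tv = row[design.loc[design["condition"] == "tumor", "sample_id"]].dropna().to_numpy()
            nv = row[design.loc[design["condition"] == "normal", "sample_id"]].dropna().to_numpy()
            n_used = len(tv) + len(nv)
            if len(tv) < 2 or len(nv) < 2:
                rows.append((locus, np.nan, np.nan, "two_sided_t", n_used, False, False))
                continue
            effect = float(tv.mean() - nv.mean())
            if np.allclose(np.concatenate([tv - tv.mean(), nv - nv.mean()]).std(), 0.0):
                p = 1.0 if np.allclose(effect, 0.0) else _P_FLOOR
                rows.append((locus, effect, p, "two_sided_t", n_used, True, True))
                continue
            p = float(stats.ttest_ind(tv, nv, equal_var=False).pvalue)
            rows.append((locus, effect, p, "two_sided_t", n_used, True, False))
    out = pd.DataFrame(
        rows, columns=["locus_id", "effect", "p_value", "test", "n_used", "tested", "degenerate"]
    )
    out["adjusted_p"] = np.nan
    tested = out["tested"].to_numpy()
    if adjust == "BH" and tested.any():
        out.loc[tested, "adjusted_p"] = multipletests(
            out.loc[tested, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    elif adjust == "none":
        out["adjusted_p"] = out["p_value"]
    return out


test_differential.__test__ = False  # not a pytest test despite the name


def fold_change(matrix: LocusQuantMatrix, design: pd.DataFrame) -> pd.Series:
    """Linear tumor/normal ratio: 2 ** (mean tumor log2 - mean normal log2)."""
    validate_design(design)
    tcols = design.loc[design["condition"] == "tumor", "sample_id"]
    ncols = design.loc[design["condition"] == "normal", "sample_id"]
    diff = matrix.values[tcols].mean(axis=1) - matrix.values[ncols].mean(axis=1)
    fc = np.power(2.0, diff)
    fc.name = "fold_change"
    return fc


def classify_tissue_specificity(
    detection: pd.DataFrame,
    ubiquitous_min: int = 15,
) -> pd.DataFrame:
    """Expression class per locus from a boolean locus x tissue frame.

    1 tissue -> tissue_specific; 2..(ubiquitous_min - 1) -> nonspecific;
    >= ubiquitous_min -> ubiquitous.  Loci detected nowhere are labelled
    ``undetected`` and should not reach this stage.
    """
    n = detection.sum(axis=1).astype(int)
    cls = pd.Series("undetected", index=detection.index, dtype=object)
    cls[n == 1] = "tissue_specific"
    cls[(n >= 2) & (n < ubiquitous_min)] = "nonspecific"
    cls[n >= ubiquitous_min] = "ubiquitous"
    return pd.DataFrame({"n_tissues_detected": n, "expression_class": cls})


def recurrence_bins(detection: pd.DataFrame, sample_dataset: pd.Series) -> pd.DataFrame:
    """Bin each locus by its within-dataset missing fraction.

    ``detection`` is boolean locus x sample; ``sample_dataset`` maps sample
    to dataset.  Bins on the missing fraction are half-open —
    [0, .25), [.25, .5), [.5, .75), [.75, 1] — labelled 0-25 .. 75-100.
    """
    rows = []
    for ds, cols in pd.Series(sample_dataset).groupby(pd.Series(sample_dataset)):
        samples = cols.index.tolist()
        frac_missing = 1.0 - detection[samples].mean(axis=1)
        binned = pd.cut(
            frac_missing,
            bins=[0, 0.25, 0.5, 0.75, 1.0 + 1e-9],
            right=False,
            labels=RECURRENCE_BINS,
        )
        for locus in detection.index:
            rows.append((locus, ds, float(frac_missing[locus]), str(binned[locus])))
    return pd.DataFrame(rows, columns=["locus_id", "dataset_id", "missing_fraction", "bin"])


def cross_dataset_overlap(
    detections: dict[str, set],
    categories: dict[str, str],
    min_datasets: int = 2,
) -> dict:
    """Share of loci detected in >= ``min_datasets`` datasets, split into
    pseudogene vs non-pseudogene.

    ``detections`` maps locus -> set of dataset IDs in which it was seen.
    """
    def share(ids):
        if not ids:
            return float("nan")
        rep = sum(1 for l in ids if len(detections[l]) >= min_datasets)
        return rep / len(ids)

    pg = [l for l in detections if categories.get(l) == "pseudogene"]
    other = [l for l in detections if categories.get(l) != "pseudogene"]
    return {
        "pseudogene_share": share(pg),
        "non_pseudogene_share": share(other),
        "n_pseudogene": len(pg),
        "n_non_pseudogene": len(other),
        "counts": {l: len(d) for l, d in detections.items()},
    }
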