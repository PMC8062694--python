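"""Dark-antigen candidate screening.

9-mer windows from novel-locus protein segments are scored by three
pluggable components — MHC class I binding, proteasomal C-terminal
cleavage, TAP transport — combined as

    combined = mhc + 0.225 * cleavage + 0.025 * tap

(the additive convention of combined MHC/cleavage/TAP predictors; a
normalized weighted-average mode is available behind a flag).  Each
combined score is expressed as a %-rank against a frozen background of
1000 random natural 9-mers sampled from a supplied proteome, and
candidates are kept when %-rank <= 0.5 and the source locus is >= 1.5-fold
upregulated in tumor (where matched normals exist).

The built-in reference scorer is a deterministic, documented toy model
with the same interface as an external predictor plugin: an anchor-position
weight matrix (positions 2 and 9) for MHC, a C-terminal residue lookup for
cleavage, and a hydropathy-mean proxy for TAP, all in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import EpitopeCandidate, EpitopeScoreConfig

# Kyte-Doolittle hydropathy, used as the TAP transport proxy
_KD = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4, "H": -3.2,
    "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5,
    "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

# anchor preference at peptide position 2 (hydrophobic B-pocket)
_ANCHOR2 = {
    "L": 1.00, "M": 0.95, "I": 0.90, "V": 0.80, "A": 0.60, "T": 0.50, "Q": 0.45,
    "F": 0.40, "S": 0.35, "Y": 0.30, "C": 0.30, "G": 0.25, "W": 0.20, "N": 0.20,
    "H": 0.15, "E": 0.12, "K": 0.10, "R": 0.10, "D": 0.05, "P": 0.02,
}

# anchor preference at the C-terminal position 9 (F-pocket)
_ANCHOR9 = {
    "V": 1.00, "L": 0.95, "I": 0.90, "F": 0.70, "M": 0.65, "Y": 0.55, "A": 0.50,
    "W": 0.40, "T": 0.30, "C": 0.28, "S": 0.22, "Q": 0.18, "K": 0.15, "R": 0.15,
    "H": 0.12, "N": 0.10, "G": 0.08, "E": 0.06, "D": 0.04, "P": 0.02,
}

# C-terminal cleavage propensity of the proteasome
_CLEAVAGE_CTERM = {
    "L": 1.00, "F": 0.95, "Y": 0.90, "W": 0.85, "M": 0.80, "A": 0.70, "V": 0.65,
    "I": 0.60, "K": 0.55, "R": 0.50, "T": 0.40, "Q": 0.35, "S": 0.30, "H": 0.28,
    "N": 0.25, "C": 0.22, "E": 0.18, "D": 0.12, "G": 0.10, "P": 0.02,
}


def reference_scorer(nine_mer: str, allele: str | None = None) -> tuple[float, float, float]:
    """Deterministic toy (mhc, cleavage, tap) scores in [0, 1]^3.

    MHC depends only on the anchor residues at positions 2 and 9; the
    ``allele`` tag is accepted for interface compatibility and ignored.
    """
    if len(nine_mer) != 9:
        raise ValueError(f"expected a 9-mer, got {nine_mer!r}")
    p = nine_mer.upper()
    mhc = 0.5 * (_ANCHOR2.get(p[1], 0.0) + _ANCHOR9.get(p[8], 0.0))
    cleavage = _CLEAVAGE_CTERM.get(p[8], 0.0)
    tap = (np.mean([_KD.get(a, 0.0) for a in p]) + 4.5) / 9.0
    return float(mhc), float(cleavage), float(tap)


def enumerate_9mers(protein: str) -> list[tuple[int, str]]:
    """All overlapping length-9 windows with their 0-based offsets."""
    return [(i, protein[i : i + 9]) for i in range(len(protein) - 8)]


def combined_score(mhc: float, cleavage: float, tap: float, cfg: EpitopeScoreConfig | None = None) -> float:
    """Combine the three component scores under the configured weights."""
    cfg = cfg or EpitopeScoreConfig()
    total = mhc + cfg.w_cleavage * cleavage + cfg.w_tap * tap
    if cfg.combination == "normalized_average":
        return total / (1.0 + cfg.w_cleavage + cfg.w_tap)
    if cfg.combination != "additive":
        raise ValueError(f"unknown combination {cfg.combination!r}")
    return total


def percent_rank(score: float, background_scores) -> float:
    """Percentile rank of ``score`` in the frozen background.

    rank = 100 * #{background >= score} / N; ties count against the query,
    and a score above the whole background ranks 0.0.
    """
    bg = np.asarray(background_scores, dtype=float)
    if bg.size == 0:
        raise ValueError("empty background")
    return float(100.0 * np.count_nonzero(bg >= score) / bg.size)


@dataclass
class Background:
    """Frozen background of natural 9-mers and their combined scores."""

    nine_mers: list[str]
    scores: np.ndarray

    @classmethod
    def build(
        cls,
        proteome: list[tuple[str, str]],
        cfg: EpitopeScoreConfig,
        scorer=reference_scorer,
    ) -> "Background":
        """Sample ``cfg.background_size`` 9-mer windows uniformly from the
        proteome (seeded by ``cfg.background_seed``) and score them."""
        windows: list[str] = []
        for _pid, seq in proteome:
            windows.extend(w for _i, w in enumerate_9mers(seq))
        if not windows:
            raise ValueError("proteome contains no 9-mer windows")
        rng = np.random.default_rng(cfg.background_seed)
        idx = rng.integers(0, len(windows), size=cfg.background_size)
        nine_mers = [windows[i] for i in idx]
        scores = np.array([combined_score(*scorer(w), cfg) for w in nine_mers])
        return cls(nine_mers=nine_mers, scores=scores)


def score_epitopes(
    locus_proteins: dict[str, list[str]],
    background: Background,
    cfg: EpitopeScoreConfig | None = None,
    scorer=reference_scorer,
    locus_fold_changes: dict[str, float] | None = None,
) -> list[EpitopeCandidate]:
    """Score every 9-mer window of every locus protein segment."""
    cfg = cfg or EpitopeScoreConfig()
    locus_fold_changes = locus_fold_changes or {}
    out = []
    for lid in sorted(locus_proteins):
        seen = set()
        for prot in locus_proteins[lid]:
            for _i, w in enumerate_9mers(prot):
                if w in seen:  # identical window within one locus
                    continue
                seen.add(w)
                mhc, clv, tap = scorer(w)
                comb = combined_score(mhc, clv, tap, cfg)
                out.append(
                    EpitopeCandidate(
                        nine_mer=w,
                        source_locus=lid,
                        mhc_score=mhc,
                        cleavage_score=clv,
                        tap_score=tap,
                        combined_score=comb,
                        percent_rank=percent_rank(comb, background.scores),
                        locus_fold_change=locus_fold_changes.get(lid),
                    )
                )
    return out


def select_candidates(
    epitopes: list[EpitopeCandidate],
    cfg: EpitopeScoreConfig | None = None,
) -> list[EpitopeCandidate]:
    """Dark-antigen selection: %-rank <= threshold AND locus fold change >=
    minimum.  The fold-change criterion applies only where a matched-normal
    fold change exists (``locus_fold_change`` is not None)."""
    cfg = cfg or EpitopeScoreConfig()
    kept = []
    for e in epitopes:
        if e.percent_rank > cfg.rank_threshold:
            continue
        if e.locus_fold_change is not None and e.locus_fold_change < cfg.fold_change_min:
            continue
        kept.append(e)
    return kept


def per_locus_summary(epitopes: list[EpitopeCandidate], cfg: EpitopeScoreConfig | None = None) -> pd.DataFrame:
    """Per-locus flag: has at least one selected 9-mer."""
    cfg = cfg or EpitopeScoreConfig()
    selected = {e.source_locus for e in select_candidates(epitopes, cfg)}
    loci = sorted({e.source_locus for e in epitopes})
    return pd.DataFrame(
        {"locus_id": loci, "has_candidate": [l in selected for l in loci]}
    )


def candidates_to_frame(cands: list[EpitopeCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "nine_mer": [c.nine_mer for c in cands],
            "locus_id": [c.source_locus for c in cands],
            "mhc_score": [c.mhc_score for c in cands],
            "cleavage_score": [c.cleavage_score for c in cands],
            "tap_score": [c.tap_score for c in cands],
            "combined_score": [c.combined_score for c in cands],
            "percent_rank": [c.percent_rank for c in cands],
            "fold_change": [c.locus_fold_change for c in cands],
        }
    )


def optimal_9mer(cfg: EpitopeScoreConfig | None = None) -> str:
    """The 9-mer maximizing the combined reference score (separable argmax).

    Useful for planting a guaranteed high scorer in synthetic fixtures."""
    cfg = cfg or EpitopeScoreConfig()
    kd_best = max(_KD, key=_KD.get)
    body = kd_best  # non-anchor positions only feed the TAP mean
    p2 = max(_ANCHOR2, key=lambda a: 0.5 * _ANCHOR2[a] + cfg.w_tap * _KD[a] / 9.0)
    p9 = max(
        _ANCHOR9,
        key=lambda a: 0.5 * _ANCHOR9[a] + cfg.w_cleavage * _CLEAVAGE_CTERM[a] + cfg.w_tap * _KD[a] / 9.0,
    )
    return body + p2 + body * 6 + p9


def pessimal_9mer(cfg: EpitopeScoreConfig | None = None) -> str:
    """The 9-mer minimizing the combined reference score."""
    cfg = cfg or EpitopeScoreConfig()
    kd_worst = min(_KD, key=_KD.get)
    p2 = min(_ANCHOR2, key=lambda a: 0.5 * _ANCHOR2[a] + cfg.w_tap * _KD[a] / 9.0)
    p9 = min(
        _ANCHOR9,
        key=lambda a: 0.5 * _ANCHOR9[a] + cfg.w_cleavage * _CLEAVAGE_CTERM[a] + cfg.w_tap * _KD[a] / 9.0,
    )
    return kd_worst + p2 + kd_worst * 6 + p9
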