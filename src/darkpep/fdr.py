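"""Novel-peptide classification and class-specific target-decoy FDR.

The novel class gets its own FDR estimate: target PSMs whose peptide occurs
in the known proteome (under I/L equivalence) or in the variant set are
removed, decoy PSMs whose peptide is a known tryptic peptide are removed,
and the decoy/target score competition runs over what remains.  This
prevents the (much higher-scoring) known class from diluting the error
estimate of the novel class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PSMRecord, PeptideVerdict
from .seqtools import collapse_il, digest_tryptic, strip_modifications

log = logging.getLogger(__name__)

_TRYPTIC_MC = 2  # missed cleavages indexed for known tryptic membership
_TRYPTIC_MIN, _TRYPTIC_MAX = 7, 45


@dataclass
class KnownIndex:
    """Substring + tryptic-peptide indexes over the known proteome and the
    variant sequences, all I/L-collapsed."""

    known_blob: str  # '*'-joined collapsed known proteins
    known_proteins: list[str]
    tryptic: set[str]
    variant_blob: str
    near_match: bool = False  # allow <=1 substitution against known proteins

    @classmethod
    def from_proteome(cls, known_proteome, variants=(), near_match: bool = False):
        prots = [collapse_il(seq) for _pid, seq in known_proteome]
        tryptic = set()
        for p in prots:
            for pep in digest_tryptic(p, _TRYPTIC_MC):
                if _TRYPTIC_MIN <= len(pep) <= _TRYPTIC_MAX:
                    tryptic.add(pep)
        vprots = [collapse_il(seq) for _vid, seq in variants]
        return cls(
            known_blob="*".join(prots),
            known_proteins=prots,
            tryptic=tryptic,
            variant_blob="*".join(vprots),
            near_match=near_match,
        )

    def _near(self, pep: str) -> bool:
        n = len(pep)
        for prot in self.known_proteins:
            for i in range(len(prot) - n + 1):
                mism = 0
                for a, b in zip(pep, prot[i : i + n]):
                    if a != b:
                        mism += 1
                        if mism > 1:
                            break
                else:
                    return True
        return False

    def classify(self, peptide: str) -> str:
        """known | variant | novel (modifications stripped, I/L collapsed)."""
        pep = collapse_il(strip_modifications(peptide))
        if not pep:
            raise ValueError("empty peptide")
        if "X" in pep:
            return "novel"  # X never matches
        if pep in self.known_blob:
            return "known"
        if self.near_match and self._near(pep):
            return "known"
        if self.variant_blob and pep in self.variant_blob:
            return "variant"
        return "novel"

    def is_known_tryptic(self, peptide: str) -> bool:
        return collapse_il(strip_modifications(peptide)) in self.tryptic


def classify_peptide(peptide: str, index: KnownIndex) -> str:
    return index.classify(peptide)


def prefilter_for_fdr(psms: list[PSMRecord], index: KnownIndex):
    """Partition PSMs for novel-class FDR.

    Removes target PSMs classifying known/variant and decoy PSMs whose
    as-read peptide is a known tryptic peptide.  Returns
    ``(novel_targets, novel_decoys, discarded)``.
    """
    novel_targets, novel_decoys, discarded = [], [], []
    for p in psms:
        if p.is_decoy:
            if index.is_known_tryptic(p.peptide):
                discarded.append(p)
            else:
                novel_decoys.append(p)
        else:
            if index.classify(p.peptide) == "novel":
                novel_targets.append(p)
            else:
                discarded.append(p)
    return novel_targets, novel_decoys, discarded


def _best_per_peptide(psms: list[PSMRecord]):
    best: dict[str, float] = {}
    count: dict[str, int] = {}
    for p in psms:
        key = collapse_il(strip_modifications(p.peptide))
        count[key] = count.get(key, 0) + 1
        if key not in best or p.score > best[key]:
            best[key] = p.score
    return best, count


def target_decoy_qvalues(target_scores: np.ndarray, decoy_scores: np.ndarray) -> np.ndarray:
    """q-values for targets against decoys.

    At a score threshold ``s``, FDR(s) = #{decoys >= s} / #{targets >= s};
    the q-value of a target at score s is the minimum FDR over all
    thresholds <= s.  Ties rank decoys above targets (a decoy at the same
    score counts against the target).  With no decoys all q-values are 0.
    """
    t = np.asarray(target_scores, dtype=float)
    d = np.sort(np.asarray(decoy_scores, dtype=float))
    if t.size == 0:
        return np.empty(0)
    if d.size == 0:
        log.warning("no decoys available: all q-values are 0")
        return np.zeros(t.size)
    order = np.argsort(t, kind="stable")  # ascending
    ts = t[order]
    n_t_ge = t.size - np.arange(t.size)  # targets >= ts[i] (ties included)
    n_d_ge = d.size - np.searchsorted(d, ts, side="left")  # decoys >= ts[i]
    fdr = n_d_ge / n_t_ge
    q_sorted = np.minimum.accumulate(fdr)  # min over thresholds <= s
    q = np.empty(t.size)
    q[order] = q_sorted
    return q


def class_specific_fdr(
    novel_targets: list[PSMRecord],
    novel_decoys: list[PSMRecord],
    alpha: float = 0.01,
    level: str = "peptide",
) -> list[PeptideVerdict]:
    """Estimate novel-class q-values and accept at ``q <= alpha``.

    ``level='peptide'`` (default) collapses PSMs to the best score per
    peptide before the target/decoy competition; ``level='psm'`` scores each
    PSM separately (verdicts then carry one row per PSM peptide occurrence's
    best score anyway, so only the competition granularity changes).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if level not in ("peptide", "psm"):
        raise ValueError(f"unknown level {level!r}")
    if not novel_targets:
        return []
    if level == "peptide":
        t_best, t_count = _best_per_peptide(novel_targets)
        d_best, _ = _best_per_peptide(novel_decoys)
        peptides = sorted(t_best)
        t_scores = np.array([t_best[p] for p in peptides])
        d_scores = np.array(sorted(d_best.values()))
    else:
        peptides = [collapse_il(strip_modifications(p.peptide)) for p in novel_targets]
        t_scores = np.array([p.score for p in novel_targets])
        d_scores = np.array([p.score for p in novel_decoys])
        t_count = {}
        for p in peptides:
            t_count[p] = t_count.get(p, 0) + 1
    q = target_decoy_qvalues(t_scores, d_scores)
    verdicts = [
        PeptideVerdict(
            peptide=pep,
            peptide_class="novel",
            best_score=float(s),
            q_value=float(qv),
            supporting_psm_count=t_count[pep],
        )
        for pep, s, qv in zip(peptides, t_scores, q)
    ]
    verdicts.sort(key=lambda v: (-v.best_score, v.peptide))
    return verdicts


def accepted_peptides(verdicts: list[PeptideVerdict], alpha: float = 0.01) -> list[PeptideVerdict]:
    return [v for v in verdicts if v.q_value is not None and v.q_value <= alpha]


def global_fdr_novel(psms: list[PSMRecord], index: KnownIndex, alpha: float = 0.01):
    """Baseline for comparison: one FDR over *all* classes, then read off the
    novel-class peptides accepted at ``q <= alpha``.

    This is the estimator the class-specific procedure improves on: the
    high-scoring known class inflates the target counts, understating the
    error rate within the novel class.
    """
    targets = [p for p in psms if not p.is_decoy]
    decoys = [p for p in psms if p.is_decoy]
    t_best, t_count = _best_per_peptide(targets)
    d_best, _ = _best_per_peptide(decoys)
    peptides = sorted(t_best)
    q = target_decoy_qvalues(
        np.array([t_best[p] for p in peptides]), np.array(sorted(d_best.values()))
    )
    out = []
    for pep, qv in zip(peptides, q):
        if qv <= alpha and index.classify(pep) == "novel":
            out.append(
                PeptideVerdict(
                    peptide=pep,
                    peptide_class="novel",
                    best_score=float(t_best[pep]),
                    q_value=float(qv),
                    supporting_psm_count=t_count[pep],
                )
            )
    return out


def verdicts_to_frame(verdicts: list[PeptideVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peptide": [v.peptide for v in verdicts],
            "class": [v.peptide_class for v in verdicts],
            "best_score": [v.best_score for v in verdicts],
            "q_value": [v.q_value for v in verdicts],
            "supporting_psm_count": [v.supporting_psm_count for v in verdicts],
        }
    )
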