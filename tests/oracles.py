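"""Independent brute-force oracles shared by the unit and acceptance tests.

Each oracle re-derives the expected result by direct enumeration, without
interval trees, vectorized rank arithmetic, or any code path shared with
the implementation it checks.
"""

import re

import numpy as np

from darkpep.seqtools import CODON_TABLE


def naive_three_frames(seq, min_len):
    """Per-codon translation with manual stop splitting."""
    out = []
    for frame in range(3):
        aa = ""
        i = frame
        while i + 3 <= len(seq):
            aa += CODON_TABLE.get(seq[i : i + 3].upper(), "X")
            i += 3
        seg_idx = 0
        for part in aa.split("*"):
            if len(part) >= min_len:
                out.append((frame, seg_idx, part))
                seg_idx += 1
    return out


def oracle_qvalues(targets, decoys):
    """Exhaustive threshold enumeration, then monotonization."""
    qs = []
    for s in targets:
        best = np.inf
        for thr in targets:
            if thr > s:
                continue
            d = sum(1 for x in decoys if x >= thr)
            t = sum(1 for x in targets if x >= thr)
            best = min(best, d / t)
        qs.append(best)
    return np.array(qs)


def oracle_percent_rank(score, background):
    return 100.0 * sum(1 for b in background if b >= score) / len(background)


def oracle_category(loc, ann):
    """Linear-scan precedence oracle for origin-category assignment."""

    def hit(iv):
        return any(min(e, iv[1]) - max(s, iv[0]) > 0 for s, e in loc.blocks)

    def pep_phase(pos):
        off = 0
        blocks = loc.blocks if loc.strand == "+" else list(reversed(loc.blocks))
        for s, e in blocks:
            if s <= pos < e:
                return (off + (pos - s)) % 3 if loc.strand == "+" else (off + (e - 1 - pos)) % 3
            off += e - s
        return None

    def cds_phase(g, pos):
        off = 0
        for s, e in g.cds:
            if s <= pos < e:
                return (off + (pos - s)) % 3 if g.strand == "+" else (off + (e - 1 - pos)) % 3
            off += e - s
        return None

    for tx in ann.transcripts.values():
        if tx.biotype == "pseudogene" and tx.chrom == loc.chrom and hit(tx.span):
            return "pseudogene"
    for tx in ann.transcripts.values():
        if tx.biotype == "lncRNA" and tx.chrom == loc.chrom and hit(tx.span):
            return "lncRNA"
    for r in ann.repeats:
        if r.chrom == loc.chrom and hit((r.start, r.end)):
            return "retroelement"
    genes = [g for g in ann.genes.values() if g.chrom == loc.chrom]
    if any(hit(iv) for g in genes for iv in g.utr5 + g.utr3):
        return "utr"
    for g in genes:
        for iv in g.cds:
            if not hit(iv):
                continue
            if g.strand != loc.strand:
                return "exonic_altframe"
            probe = None
            for s, e in sorted(loc.blocks):
                lo, hi = max(s, iv[0]), min(e, iv[1])
                if lo < hi:
                    probe = lo
                    break
            if probe is not None and cds_phase(g, probe) != pep_phase(probe):
                return "exonic_altframe"
    for g in genes:
        if any(hit(iv) for iv in g.exons) and any(hit(iv) for iv in g.introns):
            return "intron_exon_boundary"
    if any(hit(iv) for g in genes for iv in g.introns):
        return "intronic"
    if any(hit(g.upstream) for g in genes):
        return "upstream"
    if any(hit(g.downstream) for g in genes):
        return "downstream"
    return "intergenic"


def brute_force_counts(locations, sam_text, min_overlap=1, max_mismatch=1):
    """All-pairs (read, block) overlap checker."""
    counts = {loc.placement_id: 0 for loc in locations}
    for line in sam_text.splitlines():
        if not line or line.startswith("@"):
            continue
        f = line.split("\t")
        chrom, pos = f[2], int(f[3]) - 1
        span = sum(
            int(n) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", f[5]) if op in "MDN=X"
        )
        nm = None
        for t in f[11:]:
            if t.startswith("NM:i:"):
                nm = int(t[5:])
        if nm is None or nm > max_mismatch:
            continue
        for loc in locations:
            if loc.chrom != chrom:
                continue
            if any(min(pos + span, e) - max(pos, s) >= min_overlap for s, e in loc.blocks):
                counts[loc.placement_id] += 1
    return counts
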