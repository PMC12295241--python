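"""Independent brute-force reference implementations used to cross-check the
package.  Deliberately written with different machinery than the library
(regex run-finding, word expansion, per-bp scans, explicit formulas)."""

from __future__ import annotations

import itertools
import re

import numpy as np
from scipy import stats

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_RC = str.maketrans("ACGTN", "TGCAN")


def brute_force_variants(aln):
    """Per-column scanner: classify every column of each contig as
    M(atch)/D(eletion)/I(nsertion)/B(oth-gap), then find deletion runs with
    the regex ``D(?:B*D)*`` and insertion runs with ``I+`` inside the
    contig's aligned span.  Returns (deletion set, insertion set, SNP set).
    """
    ref = aln.sequences[aln.ref_id]
    # ref position at each column (position of last ref base seen)
    ref_pos_at = []
    p = 0
    for ch in ref:
        if ch != "-":
            p += 1
        ref_pos_at.append(p)

    deletions = {}
    insertions = {}
    snps = {}
    for sid, seq in aln.sequences.items():
        if sid == aln.ref_id:
            continue
        nongap = [i for i, ch in enumerate(seq) if ch != "-"]
        if not nongap:
            continue
        lo, hi = nongap[0], nongap[-1]
        cls = []
        for i in range(lo, hi + 1):
            r, c = ref[i], seq[i]
            if r != "-" and c != "-":
                cls.append("M")
                if r != c and r != "N" and c != "N":
                    snps.setdefault((ref_pos_at[i], i + 1, r, c), set()).add(sid)
            elif r != "-" and c == "-":
                cls.append("D")
            elif r == "-" and c != "-":
                cls.append("I")
            else:
                cls.append("B")
        s = "".join(cls)
        for m in re.finditer(r"D(?:B*D)*", s):
            cols = [lo + k for k in range(m.start(), m.end()) if s[k] == "D"]
            r0, r1 = ref_pos_at[cols[0]], ref_pos_at[cols[-1]]
            key = ("deletion", r0, r1, r1 - r0 + 1, cols[0] + 1, cols[-1] + 1)
            deletions.setdefault(key, set()).add(sid)
        for m in re.finditer(r"I+", s):
            cols = list(range(lo + m.start(), lo + m.end()))
            anchor = ref_pos_at[cols[0]]
            key = ("insertion", anchor, anchor, len(cols), cols[0] + 1, cols[-1] + 1)
            insertions.setdefault(key, set()).add(sid)

    return (
        {k + (frozenset(v),) for k, v in deletions.items()},
        {k + (frozenset(v),) for k, v in insertions.items()},
        {k + (frozenset(v),) for k, v in snps.items()},
    )


def variants_as_tuples(indels, snps):
    """Project the library's calls onto the oracle's tuple space."""
    dels = set()
    ins = set()
    for v in indels:
        t = (v.kind, v.ref_start, v.ref_end, v.length, v.aln_start, v.aln_end,
             v.carriers)
        (dels if v.kind == "deletion" else ins).add(t)
    snp_set = set()
    for s in snps:
        for alt, carriers in s.alts.items():
            snp_set.add((s.ref_pos, s.aln_col, s.ref_base, alt, carriers))
    return dels, ins, snp_set


def consensus_words(pattern: str) -> set[str]:
    """All concrete words of an IUPAC pattern, by cartesian expansion."""
    return {
        "".join(w) for w in itertools.product(*[IUPAC[c] for c in pattern.upper()])
    }


def brute_force_consensus_sites(seq: str, pattern: str) -> set[tuple[int, str]]:
    """(1-based ungapped start, strand) hits of a consensus on both strands,
    palindromic double hits collapsed to 'both'."""
    words = consensus_words(pattern)
    rc_words = {w.translate(_RC)[::-1] for w in words}
    w = len(pattern)
    out = set()
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        fwd = window in words
        rev = window in rc_words
        if fwd and rev:
            out.add((i + 1, "both"))
        elif fwd:
            out.add((i + 1, "+"))
        elif rev:
            out.add((i + 1, "-"))
    return out


def brute_force_matrix_sites(seq, matrix, threshold):
    """(start, strand, score) via explicit per-window loops."""
    w = len(matrix)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    maxsum = sum(max(row) for row in matrix)

    def score(window):
        tot = 0.0
        for ch, row in zip(window, matrix):
            if ch not in idx:
                return None
            tot += row[idx[ch]]
        return tot / maxsum

    out = set()
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        if "N" in window:
            continue
        f = score(window)
        r = score(window.translate(_RC)[::-1])
        hit_f = f is not None and f >= threshold
        hit_r = r is not None and r >= threshold
        if hit_f and hit_r:
            out.add((i + 1, "both", round(max(f, r), 9)))
        elif hit_f:
            out.add((i + 1, "+", round(f, 9)))
        elif hit_r:
            out.add((i + 1, "-", round(r, 9)))
    return out


def brute_force_region_membership(intervals, points, lo, hi):
    """Is any bp of inclusive [lo, hi] covered?  Per-bp linear scan."""
    covered = set(points)
    for a, b in intervals:
        covered.update(range(a, b + 1))
    return any(x in covered for x in range(lo, hi + 1))


def excel_rank_avg(values):
    """RANK.AVG-style average ranks, ascending, by counting."""
    out = []
    for v in values:
        less = sum(1 for x in values if x < v)
        equal = sum(1 for x in values if x == v)
        out.append(less + (equal + 1) / 2)
    return out


def brute_force_association(days_by_line, scores_by_line):
    """One marker-trait test recomputed with explicit formulas.

    ``days_by_line``: {line: [replicate days]}; ``scores_by_line``:
    {line: score or None}.  Returns (rho, n, p_raw)."""
    lines = [
        l for l in days_by_line
        if scores_by_line.get(l) is not None and days_by_line[l]
    ]
    means = [round(sum(days_by_line[l]) / len(days_by_line[l]), 6) for l in lines]
    ranks = excel_rank_avg(means)
    scores = [scores_by_line[l] for l in lines]
    n = len(lines)
    mr = sum(ranks) / n
    ms = sum(scores) / n
    cov = sum((r - mr) * (s - ms) for r, s in zip(ranks, scores))
    vr = sum((r - mr) ** 2 for r in ranks)
    vs = sum((s - ms) ** 2 for s in scores)
    rho = cov / np.sqrt(vr * vs)
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return rho, n, p


def brute_force_exclusive(sites, scope_lo, scope_hi):
    """Per-TF exclusivity by exhaustive filtering."""
    by_tf = {}
    for tf_id, a, b, inside in sites:
        if a < scope_lo or b > scope_hi:
            continue
        by_tf.setdefault(tf_id, []).append(inside)
    return {
        tf_id: (len(flags), sum(flags), all(flags) and len(flags) >= 1)
        for tf_id, flags in by_tf.items()
    }


def nearest_neighbour_pairs(list_a, list_b):
    out = []
    for a in list_a:
        best = None
        for b in sorted(list_b):
            if best is None or abs(a - b) < abs(a - best):
                best = b
        out.append((a, best, a - best, abs(a - best)))
    return out
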