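"""Independent oracles used by the test suite.

Each oracle re-derives a quantity by a route deliberately different
from the implementation: exhaustive enumeration of alignment paths for
the profile search, an independently written memoized affine DP for
pairwise statistics, window scans for tandem arrays, and direct
formula evaluation for the expression rules.
"""

from __future__ import annotations

import functools
import math
from typing import Sequence

NEG = float("-inf")


def enumerate_local_best(
    col_scores: Sequence[dict],
    seq: str,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Best local profile-to-sequence alignment score by enumeration.

    Alignments start and end with a match; gap runs are maximal and
    never mix insertions with deletions (the same path model as the
    implementation's DP). A gap of length k costs
    gap_open + (k-1)*gap_extend. Returns -inf when no match is
    possible.
    """
    n, L = len(col_scores), len(seq)
    best = NEG

    def rec(i: int, j: int, score: float) -> None:
        # alignment currently ends with column i matched to position j
        nonlocal best
        if score > best:
            best = score
        if i < n and j < L:
            rec(i + 1, j + 1, score + col_scores[i][seq[j]])
        for d in range(1, n - i):  # delete d columns, then match
            if i + d < n and j < L:
                cost = gap_open + (d - 1) * gap_extend
                rec(i + d + 1, j + 1, score - cost + col_scores[i + d][seq[j]])
        for k in range(1, L - j):  # insert k residues, then match
            if j + k < L and i < n:
                cost = gap_open + (k - 1) * gap_extend
                rec(i + 1, j + k + 1, score - cost + col_scores[i][seq[j + k]])

    for i0 in range(n):
        for j0 in range(L):
            rec(i0 + 1, j0 + 1, col_scores[i0][seq[j0]])
    return best


def affine_global_best(
    a: str,
    b: str,
    substitution,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Optimal global alignment score with affine gaps and free end gaps.

    Memoized three-state recursion written independently of the
    implementation's aligner. ``substitution(x, y)`` returns the match
    score; gap penalties are positive costs.
    """
    la, lb = len(a), len(b)

    @functools.lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> float:
        # best score of aligning a[i:] with b[j:], entered in `state`
        if i == la and j == lb:
            return 0.0
        if i == la:  # remaining b is a free end gap
            return 0.0
        if j == lb:  # remaining a is a free end gap
            return 0.0
        options = []
        options.append(substitution(a[i], b[j]) + rec(i + 1, j + 1, "M"))
        cost_a = gap_extend if state == "A" else gap_open
        options.append(-cost_a + rec(i + 1, j, "A"))
        cost_b = gap_extend if state == "B" else gap_open
        options.append(-cost_b + rec(i, j + 1, "B"))
        return max(options)

    # free leading end gaps: start anywhere along either sequence;
    # the all-end-gap path scores 0
    best = 0.0
    for i0 in range(la):
        for j0 in range(lb):
            if i0 > 0 and j0 > 0:
                continue  # only one sequence may have a leading end gap
            best = max(best, rec(i0, j0, "M"))
    return best


def window_scan_tags(loci, max_spacers: int):
    """Tandem clusters by quadratic window scan over chromosome ranks."""
    clusters = []
    by_chrom = {}
    for locus in loci:
        by_chrom.setdefault(locus.chromosome, []).append(locus)
    for chrom in sorted(by_chrom):
        fam = sorted(
            (l for l in by_chrom[chrom] if l.family_member), key=lambda l: l.rank
        )
        used = set()
        for s in range(len(fam)):
            if s in used:
                continue
            cluster = [fam[s]]
            for t in range(s + 1, len(fam)):
                if fam[t].rank - cluster[-1].rank - 1 <= max_spacers:
                    cluster.append(fam[t])
                    used.add(t)
                else:
                    break
            if len(cluster) >= 2:
                clusters.append(tuple(cluster))
    return clusters


def ddct_formula(ct_t_test, ct_r_test, ct_t_cal, ct_r_cal) -> float:
    return 2.0 ** -((ct_t_test - ct_r_test) - (ct_t_cal - ct_r_cal))


def spliced_intron_positions(cds_segments, strand, domain_span):
    """Exon-walk oracle: per-base provenance of the spliced CDS.

    Walks the CDS base by base in transcript orientation, recording the
    genomic position of each base; an intron sits wherever consecutive
    CDS bases are not genomically adjacent. Positions are returned in
    (codon offset from domain start, phase) form.
    """
    genomic_positions = []
    for a, b in cds_segments:
        rng = range(a, b + 1) if strand == "+" else range(b, a - 1, -1)
        genomic_positions.extend(rng)
    step = 1 if strand == "+" else -1
    dstart, dend = domain_span
    lo = (dstart - 1) * 3
    hi = (dend - dstart + 1) * 3
    out = []
    for idx in range(1, len(genomic_positions)):
        if genomic_positions[idx] - genomic_positions[idx - 1] != step:
            d = idx - lo
            if 0 < d < hi:
                out.append((d // 3, d % 3))
    return out
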