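"""Independent oracles used to cross-check the implementation.

Everything here is deliberately written from first principles — exact
integer arithmetic for the hypergeometric tail, an erfc-based normal CDF
with bisection inverse, and a per-read CIGAR walk for pileup counts — so
the checks do not share code paths (or scipy routines) with the package.
"""

from __future__ import annotations

import math
from fractions import Fraction

import pysam


def fisher_greater_exact(a: int, b: int, c: int, d: int) -> float:
    """Exact one-sided (greater) Fisher p for [[a, b], [c, d]] by direct
    enumeration of the hypergeometric upper tail with integer arithmetic."""
    row1 = a + b
    successes = a + c
    total = a + b + c + d
    denom = math.comb(total, row1)
    num = 0
    for x in range(a, min(successes, row1) + 1):
        num += math.comb(successes, x) * math.comb(total - successes, row1 - x)
    return float(Fraction(num, denom))


def normal_cdf(z: float) -> float:
    return 0.5 * math.erfc(-z / math.sqrt(2.0))


def normal_quantile(p: float) -> float:
    """Phi^-1 by bisection on the erfc-based CDF (no scipy)."""
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if normal_cdf(mid) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def stouffer_ref(p_fwd: float, p_rev: float) -> float:
    p_fwd = min(max(p_fwd, 1e-300), 1 - 1e-16)
    p_rev = min(max(p_rev, 1e-300), 1 - 1e-16)
    z = (normal_quantile(1 - p_fwd) + normal_quantile(1 - p_rev)) / math.sqrt(2)
    return 1.0 - normal_cdf(z)


def min_alt_bruteforce(
    depth: int, model_alt: int, model_ref: int, alpha: float, n_tests: int
) -> int | None:
    """First-significant search evaluating every total alt count from 1
    upward with the exact Fisher oracle and the erfc Stouffer oracle."""
    half = depth // 2
    c_f, c_r = (model_alt + 1) // 2, model_alt // 2
    d_f, d_r = (model_ref + 1) // 2, model_ref // 2
    for a in range(1, depth + 1):
        a_f, a_r = (a + 1) // 2, a // 2
        if a_f > half:
            return None
        p_f = fisher_greater_exact(a_f, half - a_f, c_f, d_f)
        p_r = fisher_greater_exact(a_r, half - a_r, c_r, d_r)
        if stouffer_ref(p_f, p_r) < alpha / n_tests:
            return a
    return None


def naive_strand_counts(
    bam_path: str,
    chrom: str,
    pos: int,
    *,
    min_baseq: int = 0,
    min_mapq: int = 20,
) -> dict[str, dict[str, int]]:
    """Strand-split base counts at one 1-based position by walking each
    read's CIGAR explicitly (no get_aligned_pairs, no pileup engine)."""
    fwd = dict.fromkeys("ACGT", 0)
    rev = dict.fromkeys("ACGT", 0)
    consumes_query = {0, 1, 4, 7, 8}  # M, I, S, =, X
    consumes_ref = {0, 2, 3, 7, 8}  # M, D, N, =, X
    aligned = {0, 7, 8}  # M, =, X
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for read in bam.fetch(chrom, pos - 1, pos):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_qcfail
                or read.is_duplicate
            ):
                continue
            if read.mapping_quality <= min_mapq:
                continue
            rpos = read.reference_start
            qpos = 0
            for op, length in read.cigartuples:
                if op in aligned and rpos <= pos - 1 < rpos + length:
                    offset = (pos - 1) - rpos
                    q = qpos + offset
                    if read.query_qualities is None or read.query_qualities[q] >= min_baseq:
                        base = read.query_sequence[q]
                        if base in "ACGT":
                            (rev if read.is_reverse else fwd)[base] += 1
                    break
                if op in consumes_query:
                    qpos += length
                if op in consumes_ref:
                    rpos += length
    return {"fwd": fwd, "rev": rev}
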