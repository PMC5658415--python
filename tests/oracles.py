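"""Independent reference implementations used only for cross-checking.

These deliberately use different computational strategies from the package:
brute-force pair/quadruple enumeration with boolean coverage arrays for the
inversion scanner, and high-precision Decimal summation for the binomial
tail.  They are slow and only suitable for small inputs.
"""

from __future__ import annotations

import math
from decimal import Decimal, getcontext

import numpy as np


def binomial_tail_decimal(k: int, n: int, p: float, prec: int = 60) -> Decimal:
    """P(X >= k) by direct summation in 60-digit decimal arithmetic."""
    getcontext().prec = prec
    P = Decimal(p)  # exact binary-to-decimal conversion of the float
    Q = Decimal(1) - P
    total = Decimal(0)
    for i in range(k, n + 1):
        total += Decimal(math.comb(n, i)) * P**i * Q**(n - i)
    return total


def brute_force_scan(rows, tolerance=5000, min_flank=1000, min_call_size=1000):
    """Enumerate all (forward, reverse) segment pairs, test the adjacency
    and orientation predicate directly, and validate every candidate call
    with a per-base reverse-coverage array.

    Returns the set of paired-call intervals {(ref_id, start, end)}.
    Mirrors the published-pattern semantics: an F|R junction at b1 and an
    R|F junction at b2 bound a call [b1+1, b2] when the interval between
    them is reverse-covered with no gap above the tolerance.  When several
    contig pairs support one junction the longest-flank pair wins; each
    junction is consumed by at most one call, innermost F|R first.
    """
    by_ref = {}
    for r in rows:
        by_ref.setdefault(r.ref_id, []).append(r)

    out = set()
    for ref_id, group in by_ref.items():
        fwd = [r for r in group if not r.is_reverse]
        rev = [r for r in group if r.is_reverse]

        # every F|R and R|F junction, by exhaustive pair enumeration
        fr, rf = {}, {}  # junction pos -> best total flank length
        for f in group:
            for r in group:
                if f is r or f.is_reverse == r.is_reverse:
                    continue
                gap = r.ref_start - f.ref_end - 1
                if not -tolerance <= gap <= tolerance:
                    continue
                flank = f if not f.is_reverse else r
                if flank.ref_end - flank.ref_start + 1 < min_flank:
                    continue
                target = fr if not f.is_reverse else rf
                target[f.ref_end] = True

        if not rev:
            continue
        lo = min(r.ref_start for r in rev)
        hi = max(r.ref_end for r in rev)
        covered = np.zeros(hi - lo + 2 + 2 * tolerance, dtype=bool)
        off = lo - tolerance - 1  # covered[i] represents position off + 1 + i
        for r in rev:
            covered[r.ref_start - off - 1: r.ref_end - off] = True

        def cover_ok(start, end):
            if end < lo - tolerance or start > hi + tolerance:
                return False
            run = 0
            for pos in range(start, end + 1):
                idx = pos - off - 1
                hit = covered[idx] if 0 <= idx < len(covered) else False
                if hit:
                    run = 0
                else:
                    run += 1
                    if run > tolerance:
                        return False
            return True

        used_fr, used_rf = set(), set()
        # innermost F|R first; each takes the farthest reverse-covered R|F
        for b1 in sorted(fr, reverse=True):
            for b2 in sorted(rf, reverse=True):
                if b2 in used_rf or b2 - b1 < min_call_size:
                    continue
                if cover_ok(b1 + 1, b2):
                    out.add((ref_id, b1 + 1, b2))
                    used_fr.add(b1)
                    used_rf.add(b2)
                    break
    return out
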