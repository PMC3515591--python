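"""Brute-force reference implementations used for validation.

Each function here recomputes a quantity by direct enumeration or
summation, independently of the optimized code path it is used to
check. They are deliberately simple and slow; none is called by the
pipeline itself.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from . import fold as _fold


# ---------------------------------------------------------------------------
# folding: exhaustive enumeration of nested structures
# ---------------------------------------------------------------------------

def enumerate_structures(seq: str):
    """Yield every valid nested pair set for `seq` (as a dict), including
    the open chain. Valid: canonical/wobble pairs only, every pair
    encloses at least MIN_HAIRPIN bases, no pseudoknots."""
    enc = _fold.encode(seq)
    n = len(enc)

    @lru_cache(maxsize=None)
    def region(i, j):
        # list of tuples of (a,b) pairs within [i, j]
        if j - i < _fold.MIN_HAIRPIN + 1:
            return [()]
        out = list(region(i + 1, j))
        for k in range(i + _fold.MIN_HAIRPIN + 1, j + 1):
            if _fold._PAIR_IDX[enc[i], enc[k]] < 0:
                continue
            for inner in region(i + 1, k - 1):
                for rest in region(k + 1, j):
                    out.append(((i, k),) + inner + rest)
        return out

    for tup in region(0, n - 1):
        pairs = {}
        for a, b in tup:
            pairs[a], pairs[b] = b, a
        yield pairs


def mfe_by_enumeration(seq: str):
    """(mfe kcal/mol, best pair dict) by scoring every nested structure
    with the loop-decomposition scorer. Open chain scores 0."""
    best_e, best_p = 0, {}
    for pairs in enumerate_structures(seq):
        e = _fold.structure_energy(seq, pairs)
        if e < best_e:
            best_e, best_p = e, pairs
    return best_e / 100.0, best_p


# ---------------------------------------------------------------------------
# Audic-Claverie: direct log-space summation
# ---------------------------------------------------------------------------

def _log_q(k: int, x: int, t: float) -> float:
    """log of q(k|x) = t^k (x+k)! / (x! k! (1+t)^(x+k)), t = N2/N1."""
    return (k * math.log(t)
            + math.lgamma(x + k + 1) - math.lgamma(x + 1) - math.lgamma(k + 1)
            - (x + k) * math.log1p(t))


def ac_pvalue_by_summation(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided p by explicit summation of the conditional measure.

    lower = sum_{k<=y} q(k|x); the measure totals (1+t), so the upper
    tail is (1+t) - lower + q(y). p = min(1, 2 min(lower, upper)).
    """
    t = n2 / n1
    logs = [_log_q(k, x, t) for k in range(0, y + 1)]
    m = max(logs)
    lower = math.exp(m) * sum(math.exp(v - m) for v in logs)
    upper = (1.0 + t) - lower + math.exp(_log_q(y, x, t))
    return min(1.0, 2.0 * min(lower, upper))


# ---------------------------------------------------------------------------
# target rules: direct re-evaluation of the five criteria
# ---------------------------------------------------------------------------

def target_rules_direct(states) -> bool:
    """Accept/reject a duplex state vector ('m'atch, 'w'obble, 'x' mismatch)
    by checking each published criterion one at a time, verbatim:
      (i)   weighted mismatches <= 4 (wobble = 0.5)
      (ii)  no run of more than two adjacent mismatches
      (iii) no two adjacent mismatches within positions 2-12
      (iv)  no mismatch at position 10 or 11
      (v)   weighted mismatches in positions 1-12 <= 2.5
    Positions are 1-based from the miRNA 5' end."""
    w = {"m": 0.0, "w": 0.5, "x": 1.0}
    if sum(w[s] for s in states) > 4.0:
        return False
    run = 0
    for s in states:
        run = run + 1 if s == "x" else 0
        if run > 2:
            return False
    for p in range(2, 12):  # pair of positions (p, p+1) both in 2..12
        if states[p - 1] == "x" and states[p] == "x":
            return False
    if "x" in (states[9], states[10]):
        return False
    if sum(w[s] for s in states[:12]) > 2.5:
        return False
    return True


# ---------------------------------------------------------------------------
# genome alignment: sliding-window scan
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def align_by_scan(tag: str, genome: str, max_mismatch: int = 2):
    """All ungapped alignments of tag (or its reverse complement) with
    <= max_mismatch substitutions, as (start0, strand, mismatches)."""
    hits = []
    rc = tag.translate(_COMP)[::-1]
    L = len(tag)
    for start in range(0, len(genome) - L + 1):
        window = genome[start:start + L]
        for strand, query in (("+", tag), ("-", rc)):
            mm = sum(1 for a, b in zip(query, window) if a != b)
            if mm <= max_mismatch:
                hits.append((start, strand, mm))
    return hits
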