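"""RNA secondary-structure prediction by free-energy minimization.

Implements a Zuker-style dynamic program over a nearest-neighbor energy
model: Turner-style dinucleotide stacking energies plus size-dependent
hairpin/bulge/internal-loop penalties and an affine multiloop term.
Energies are handled internally as integer centi-kcal/mol so that the DP
and any independent re-scoring of a structure agree exactly.

The model deliberately omits dangling ends, terminal-AU penalties,
special tetraloops and loop sequence dependence: hairpin classification
for miRNA precursor calling needs stable stem detection, not
chemically exact free energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Energy model (centi-kcal/mol, 37 C)
# ---------------------------------------------------------------------------

INF = 1 << 28
MIN_HAIRPIN = 3          # minimal unpaired bases in a hairpin loop
MAX_INTERIOR = 30        # cap on total unpaired bases in bulge/internal loops
_LOOP_EXTRAP = 107       # 1.75 * R * T in centi-kcal (1.079 kcal/mol at 37 C)

# base encoding: A=0 C=1 G=2 U/T=3
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}

# pair indices: 0 CG, 1 GC, 2 GU, 3 UG, 4 AU, 5 UA, -1 not pairable
_PAIR_IDX = -np.ones((5, 5), dtype=np.int64)
for _k, (_a, _b) in enumerate([(1, 2), (2, 1), (2, 3), (3, 2), (0, 3), (3, 0)]):
    _PAIR_IDX[_a, _b] = _k

_PAIR_NAMES = ["CG", "GC", "GU", "UG", "AU", "UA"]

# stack[p][q]: pair p=(i,j) stacked on q=(i+1,j-1); Watson-Crick block from
# the Xia/Turner nearest-neighbor set, wobble-involving stacks approximate.
_STACK_KCAL = {
    ("CG", "CG"): -3.26, ("CG", "GC"): -3.42, ("CG", "GU"): -2.11,
    ("CG", "UG"): -1.41, ("CG", "AU"): -2.11, ("CG", "UA"): -2.08,
    ("GC", "CG"): -2.36, ("GC", "GC"): -3.26, ("GC", "GU"): -1.53,
    ("GC", "UG"): -2.51, ("GC", "AU"): -2.35, ("GC", "UA"): -2.24,
    ("GU", "CG"): -2.51, ("GU", "GC"): -1.41, ("GU", "GU"): -0.50,
    ("GU", "UG"): +1.29, ("GU", "AU"): -1.27, ("GU", "UA"): -1.36,
    ("UG", "CG"): -1.53, ("UG", "GC"): -2.11, ("UG", "GU"): +0.30,
    ("UG", "UG"): -0.50, ("UG", "AU"): -1.00, ("UG", "UA"): -0.90,
    ("AU", "CG"): -2.24, ("AU", "GC"): -2.08, ("AU", "GU"): -0.90,
    ("AU", "UG"): -1.36, ("AU", "AU"): -0.93, ("AU", "UA"): -1.10,
    ("UA", "CG"): -2.35, ("UA", "GC"): -2.11, ("UA", "GU"): -1.00,
    ("UA", "UG"): -1.27, ("UA", "AU"): -1.33, ("UA", "UA"): -0.93,
}
_STACK = np.zeros((6, 6), dtype=np.int64)
for (_p, _q), _e in _STACK_KCAL.items():
    _STACK[_PAIR_NAMES.index(_p), _PAIR_NAMES.index(_q)] = round(_e * 100)

# loop initiation penalties, indexed by loop size (centi-kcal)
_HAIRPIN_TAB = np.array([INF, INF, INF, 540, 560, 570, 540, 600, 550, 640],
                        dtype=np.int64)
_BULGE_TAB = np.array([INF, 380, 280, 320, 360, 400, 440], dtype=np.int64)
_INTERNAL_TAB = np.array([INF, INF, 150, 160, 170, 200, 210], dtype=np.int64)

# affine multiloop: a + b * (#branches incl. closing) + c * (#unpaired)
ML_A, ML_B, ML_C = 340, 40, 10


@njit(cache=False)
def _loop_tab_energy(tab, size):
    """Size penalty with Jacobson-Stockmayer log extrapolation."""
    last = len(tab) - 1
    if size <= last:
        return tab[size]
    return tab[last] + np.int64(_LOOP_EXTRAP * math.log(size / last))


def hairpin_energy(size: int) -> int:
    if size < MIN_HAIRPIN:
        return INF
    return int(_loop_tab_energy(_HAIRPIN_TAB, size))


def interior_energy(pi: int, pk: int, s1: int, s2: int) -> int:
    """Energy of the loop between pair p=(i,j) and inner pair (k,l);
    s1, s2 are unpaired counts on the 5' and 3' sides."""
    if s1 == 0 and s2 == 0:
        return int(_STACK[pi, pk])
    if s1 == 0 or s2 == 0:
        return int(_loop_tab_energy(_BULGE_TAB, s1 + s2))
    return int(_loop_tab_energy(_INTERNAL_TAB, s1 + s2))


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string (A=0, C=1, G=2, U/T=3)."""
    try:
        return np.array([_BASE_CODE[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc} in sequence") from exc


# ---------------------------------------------------------------------------
# Zuker fill (numba kernel)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _fill(enc, pair_idx, stack, hairpin_tab, bulge_tab, internal_tab,
          ml_a, ml_b, ml_c):
    n = len(enc)
    V = np.full((n, n), INF, dtype=np.int64)
    WM = np.full((n, n), INF, dtype=np.int64)
    for d in range(1, n):
        for i in range(0, n - d):
            j = i + d
            a, b = enc[i], enc[j]
            p = pair_idx[a, b] if (a < 4 and b < 4) else -1
            if p >= 0 and d > MIN_HAIRPIN:
                best = _loop_tab_energy(hairpin_tab, d - 1)
                # stack / bulge / internal
                kmax = j - MIN_HAIRPIN - 1
                for k in range(i + 1, kmax + 1):
                    s1 = k - i - 1
                    if s1 > MAX_INTERIOR:
                        break
                    lmin = k + MIN_HAIRPIN + 1
                    lo = j - 1 - (MAX_INTERIOR - s1)
                    if lo > lmin:
                        lmin = lo
                    for l in range(j - 1, lmin - 1, -1):
                        if V[k, l] >= INF:
                            continue
                        q = pair_idx[enc[k], enc[l]]
                        if q < 0:
                            continue
                        s2 = j - l - 1
                        if s1 == 0 and s2 == 0:
                            e = stack[p, q]
                        elif s1 == 0 or s2 == 0:
                            e = _loop_tab_energy(bulge_tab, s1 + s2)
                        else:
                            e = _loop_tab_energy(internal_tab, s1 + s2)
                        t = V[k, l] + e
                        if t < best:
                            best = t
                # multiloop closure: >=2 branches inside
                m = INF
                for k in range(i + 2, j - 1):
                    if WM[i + 1, k - 1] < INF and WM[k, j - 1] < INF:
                        t = WM[i + 1, k - 1] + WM[k, j - 1]
                        if t < m:
                            m = t
                if m < INF and ml_a + ml_b + m < best:
                    best = ml_a + ml_b + m
                V[i, j] = best
            # WM: segment inside a multiloop carrying >=1 branch
            wm = INF
            if WM[i, j - 1] < INF:
                wm = WM[i, j - 1] + ml_c
            if WM[i + 1, j] < INF and WM[i + 1, j] + ml_c < wm:
                wm = WM[i + 1, j] + ml_c
            if V[i, j] < INF and V[i, j] + ml_b < wm:
                wm = V[i, j] + ml_b
            for k in range(i + 1, j + 1):
                if WM[i, k - 1] < INF and WM[k, j] < INF:
                    t = WM[i, k - 1] + WM[k, j]
                    if t < wm:
                        wm = t
            WM[i, j] = wm
    # exterior
    W = np.zeros(n + 1, dtype=np.int64)
    for j in range(n):
        w = W[j]  # leave j unpaired (W is 1-based: W[j+1] for prefix ..j)
        for i in range(0, j):
            if V[i, j] < INF and W[i] + V[i, j] < w:
                w = W[i] + V[i, j]
        W[j + 1] = w
    return V, WM, W


# ---------------------------------------------------------------------------
# traceback (python; recomputes the winning case at each step)
# ---------------------------------------------------------------------------

def _traceback(enc, V, WM, W):
    n = len(enc)
    pairs: dict[int, int] = {}
    tasks: list[tuple[str, int, int]] = []
    # exterior
    j = n - 1
    while j >= 0:
        if W[j + 1] == W[j]:
            j -= 1
            continue
        found = False
        for i in range(0, j):
            if V[i, j] < INF and W[i] + V[i, j] == W[j + 1]:
                tasks.append(("V", i, j))
                j = i - 1
                found = True
                break
        if not found:  # numerical impossibility with ints
            raise AssertionError("exterior traceback failed")
    while tasks:
        kind, i, j = tasks.pop()
        if kind == "V":
            pairs[i] = j
            pairs[j] = i
            p = _PAIR_IDX[enc[i], enc[j]]
            if V[i, j] == _loop_tab_energy(_HAIRPIN_TAB, j - i - 1):
                continue
            done = False
            for k in range(i + 1, j - MIN_HAIRPIN):
                s1 = k - i - 1
                if s1 > MAX_INTERIOR:
                    break
                lstop = max(k + MIN_HAIRPIN + 1, j - 1 - (MAX_INTERIOR - s1)) - 1
                for l in range(j - 1, lstop, -1):
                    if V[k, l] >= INF:
                        continue
                    q = _PAIR_IDX[enc[k], enc[l]]
                    if q < 0:
                        continue
                    s2 = j - l - 1
                    e = interior_energy(p, q, s1, s2)
                    if e < INF and V[k, l] + e == V[i, j]:
                        tasks.append(("V", k, l))
                        done = True
                        break
                if done:
                    break
            if done:
                continue
            for k in range(i + 2, j - 1):
                if (WM[i + 1, k - 1] < INF and WM[k, j - 1] < INF and
                        ML_A + ML_B + WM[i + 1, k - 1] + WM[k, j - 1] == V[i, j]):
                    tasks.append(("M", i + 1, k - 1))
                    tasks.append(("M", k, j - 1))
                    done = True
                    break
            if not done:
                raise AssertionError("V traceback failed")
        else:  # WM segment
            while True:
                if V[i, j] < INF and V[i, j] + ML_B == WM[i, j]:
                    tasks.append(("V", i, j))
                    break
                if j > i and WM[i, j - 1] < INF and WM[i, j - 1] + ML_C == WM[i, j]:
                    j -= 1
                    continue
                if j > i and WM[i + 1, j] < INF and WM[i + 1, j] + ML_C == WM[i, j]:
                    i += 1
                    continue
                split = False
                for k in range(i + 1, j + 1):
                    if (WM[i, k - 1] < INF and WM[k, j] < INF and
                            WM[i, k - 1] + WM[k, j] == WM[i, j]):
                        tasks.append(("M", i, k - 1))
                        i, j = k, j
                        split = True
                        break
                if split:
                    continue
                raise AssertionError("WM traceback failed")
    return pairs


# ---------------------------------------------------------------------------
# public surface
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldResult:
    sequence: str
    structure: str          # dot-bracket
    mfe: float              # kcal/mol, <= 0
    pairs: dict             # position -> partner, 0-based, symmetric

    def pair_of(self, i: int):
        return self.pairs.get(i)


def fold(sequence: str, max_len: int = 400) -> FoldResult:
    """Minimum-free-energy structure of an RNA (or DNA-alphabet) string.

    Deterministic: ties are broken by a fixed traceback order. Sequences
    with no possible canonical pair fold to the open chain at 0 kcal/mol.
    """
    if len(sequence) > max_len:
        raise ValueError(f"sequence longer than {max_len} nt")
    enc = encode(sequence)
    n = len(enc)
    if n == 0:
        return FoldResult("", "", 0.0, {})
    V, WM, W = _fill(enc, _PAIR_IDX, _STACK, _HAIRPIN_TAB, _BULGE_TAB,
                     _INTERNAL_TAB, ML_A, ML_B, ML_C)
    mfe_c = int(W[n])
    if mfe_c >= 0:
        return FoldResult(sequence, "." * n, 0.0, {})
    pairs = _traceback(enc, V, WM, W)
    db = ["."] * n
    for i, j in pairs.items():
        if i < j:
            db[i], db[j] = "(", ")"
    return FoldResult(sequence, "".join(db), mfe_c / 100.0, pairs)


def pairs_from_dotbracket(db: str) -> dict:
    stack, pairs = [], {}
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pairs[i], pairs[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pairs


def structure_energy(sequence: str, pairs: dict) -> int:
    """Score a complete structure (centi-kcal) by loop decomposition.

    Independent of the DP: walks the pair set, classifies every loop
    closed by a pair (hairpin / stack / bulge / internal / multiloop)
    and sums the model terms. The exterior loop contributes zero.
    Returns INF-scale values only for structures outside the model
    (a pair enclosing fewer than MIN_HAIRPIN bases with no children).
    """
    enc = encode(sequence)
    total = 0
    opening = sorted(i for i, j in pairs.items() if i < j)
    for i in opening:
        j = pairs[i]
        p = _PAIR_IDX[enc[i], enc[j]]
        if p < 0:
            return INF
        # immediate children of (i, j)
        children = []
        k = i + 1
        while k < j:
            if k in pairs and pairs[k] > k:
                children.append((k, pairs[k]))
                k = pairs[k] + 1
            else:
                k += 1
        if not children:
            total += hairpin_energy(j - i - 1)
        elif len(children) == 1:
            (k, l) = children[0]
            q = _PAIR_IDX[enc[k], enc[l]]
            total += interior_energy(p, q, k - i - 1, j - l - 1)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
            total += ML_A + ML_B * (1 + len(children)) + ML_C * unpaired
        if total >= INF:
            return INF
    return total
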