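"""Rule-based plant miRNA target prediction.

An ungapped duplex between the miRNA (5'->3') and a same-length
transcript window is scored position by position: Watson-Crick pairing
is a match, G:U in either orientation a wobble, anything else a
mismatch. A wobble counts 0.5 toward the weighted totals but, by
default, is not a 'mismatch' for the adjacency and positional rules
(Allen-style scoring); strict_wobble=True treats it as one everywhere.

Acceptance requires all five of, positions counted from the miRNA 5'
end:
  (i)   weighted mismatches <= 4 over the duplex
  (ii)  no more than two adjacent mismatches anywhere
  (iii) no adjacent mismatches within positions 2-12
  (iv)  no mismatch at positions 10-11
  (v)   weighted mismatches within positions 1-12 <= 2.5
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import to_rna

_PAIR_STATE = {}
for _m, _t in [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]:
    _PAIR_STATE[(_m, _t)] = "m"
_PAIR_STATE[("G", "U")] = "w"
_PAIR_STATE[("U", "G")] = "w"

_WEIGHT = {"m": 0.0, "w": 0.5, "x": 1.0}
STATE_GLYPH = {"m": "|", "w": "o", "x": "x"}

CRITERIA = ("i", "ii", "iii", "iv", "v")


@dataclass(frozen=True)
class TargetAlignment:
    mirna_id: str
    transcript_id: str
    start: int                 # 1-based inclusive on the transcript
    end: int
    states: tuple              # per miRNA position 1..L, 'm'/'w'/'x'

    @property
    def weighted_mismatches(self) -> float:
        return sum(_WEIGHT[s] for s in self.states)

    @property
    def seed_weighted(self) -> float:
        return sum(_WEIGHT[s] for s in self.states[:12])

    @property
    def state_string(self) -> str:
        return "".join(STATE_GLYPH[s] for s in self.states)


def align_site(mirna_seq: str, window: str, mirna_id: str = "",
               transcript_id: str = "", start: int = 1) -> TargetAlignment:
    """Pairing states of a miRNA against one transcript window.

    The window is the transcript slice 5'->3'; miRNA position i pairs
    with window base L-i+1 (antiparallel duplex). Lengths must match.
    """
    m = to_rna(mirna_seq)
    w = to_rna(window)
    if len(m) != len(w):
        raise ValueError("window length must equal miRNA length")
    L = len(m)
    states = tuple(_PAIR_STATE.get((m[i], w[L - 1 - i]), "x") for i in range(L))
    return TargetAlignment(mirna_id, transcript_id, start, start + L - 1, states)


def accept(alignment: TargetAlignment, strict_wobble: bool = False):
    """(True, None) if the duplex passes all five criteria, else
    (False, first violated criterion in order i..v)."""
    states = alignment.states
    is_mm = [s == "x" or (strict_wobble and s == "w") for s in states]
    if sum(_WEIGHT[s] for s in states) > 4.0:
        return False, "i"
    run = 0
    for flag in is_mm:
        run = run + 1 if flag else 0
        if run > 2:
            return False, "ii"
    for p in range(2, 12):   # adjacent pair (p, p+1), both within 2..12
        if is_mm[p - 1] and is_mm[p]:
            return False, "iii"
    if is_mm[9] or is_mm[10]:
        return False, "iv"
    if sum(_WEIGHT[s] for s in states[:12]) > 2.5:
        return False, "v"
    return True, None


def scan_transcripts(mirnas: dict, transcripts: dict,
                     strict_wobble: bool = False) -> pd.DataFrame:
    """Scan every window of every transcript for every miRNA.

    mirnas: id -> mature sequence; transcripts: id -> sequence. Returns
    accepted hits sorted by (transcript, position), with the weighted
    score and the per-position state string.
    """
    rows = []
    for tid in sorted(transcripts):
        tseq = to_rna(transcripts[tid])
        for mid in sorted(mirnas):
            mseq = to_rna(mirnas[mid])
            L = len(mseq)
            for s0 in range(0, len(tseq) - L + 1):
                ali = align_site(mseq, tseq[s0:s0 + L], mid, tid, s0 + 1)
                if ali.weighted_mismatches > 4.0:
                    continue
                ok, _why = accept(ali, strict_wobble=strict_wobble)
                if ok:
                    rows.append((mid, tid, ali.start, ali.end,
                                 ali.weighted_mismatches, ali.state_string))
    df = pd.DataFrame(rows, columns=["mirna_id", "transcript_id", "start",
                                     "end", "weighted_mismatches", "states"])
    return df.sort_values(["transcript_id", "start", "mirna_id"],
                          kind="mergesort").reset_index(drop=True)


def per_mirna_target_counts(hits: pd.DataFrame) -> pd.Series:
    if hits.empty:
        return pd.Series(dtype=int)
    return hits.groupby("mirna_id").transcript_id.nunique()
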