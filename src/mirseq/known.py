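"""Known mature miRNA identification.

Tags are compared against a mature-miRNA reference allowing up to two
substitutions and a +-2 nt end shift (isomiR-style 5'/3' offsets). Each
tag is credited to exactly one best mature (fewest mismatches, then
smallest |offset|, then lexicographic id), keeping the category and
count partitions consistent. U/T equivalence is enforced before any
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import to_dna, to_rna


@dataclass(frozen=True)
class MatureMiRNA:
    id: str
    family: str
    seq: str          # RNA alphabet
    species: str = ""

    def __post_init__(self):
        if not 18 <= len(self.seq) <= 26:
            raise ValueError(f"{self.id}: mature length outside 18-26")
        if set(to_rna(self.seq)) - set("ACGU"):
            raise ValueError(f"{self.id}: invalid alphabet")


@dataclass(frozen=True)
class KnownHit:
    tag: str
    mature_id: str
    family: str
    mismatches: int
    offset: int       # tag start minus mature start, in nt


def load_mature_fasta(path) -> list:
    """Mature reference with '>id family species' headers."""
    from Bio import SeqIO
    db = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        family = parts[1] if len(parts) > 1 else _family_of(rec.id)
        species = parts[2] if len(parts) > 2 else ""
        db.append(MatureMiRNA(rec.id, family, to_rna(str(rec.seq)), species))
    return db


def _family_of(mature_id: str) -> str:
    """miR156a-5p -> miR156 style family inference."""
    core = mature_id.split("-")[0] if not mature_id.lower().startswith(("mir", "ppe")) else mature_id
    import re
    m = re.search(r"(mir[a-z]*)[-]?(\d+)", core, flags=re.IGNORECASE)
    return f"miR{m.group(2)}" if m else mature_id


def _compare(tag: str, mature: str, offset: int, cap: int):
    """Mismatches of tag vs mature at the given start offset: mismatched
    overlapping bases plus any tag bases hanging off the mature."""
    L, M = len(tag), len(mature)
    mm = 0
    overlap = 0
    for i in range(L):
        j = i + offset
        if 0 <= j < M:
            overlap += 1
            if tag[i] != mature[j]:
                mm += 1
        else:
            mm += 1
        if mm > cap:
            return mm
    return mm


def match_known(tag: str, mature_db, max_mm: int = 2, max_shift: int = 2):
    """Best KnownHit for a tag, or None.

    Equal-length windows are compared at every end offset within
    +-max_shift; best = fewest mismatches, ties by smallest |offset|,
    then lexicographic mature id.
    """
    tag_dna = to_dna(tag)
    best = None
    for mat in mature_db:
        mseq = to_dna(mat.seq)
        for off in range(-max_shift, max_shift + 1):
            mm = _compare(tag_dna, mseq, off, max_mm)
            if mm > max_mm:
                continue
            key = (mm, abs(off), mat.id)
            if best is None or key < best[0]:
                best = (key, KnownHit(tag_dna, mat.id, mat.family, mm, off))
    return best[1] if best else None


def match_known_bulk(tags, mature_db, max_mm: int = 2,
                     max_shift: int = 2) -> dict:
    """Vectorized match_known over many tags: tag -> KnownHit.

    Tags are grouped by length and compared to every mature at every
    offset with one numpy comparison per (mature, offset, length
    group); candidate order reproduces the scalar tie-breaking
    (fewest mismatches, then smallest |offset|, then mature id).
    """
    import numpy as np
    tags = [to_dna(t) for t in tags]
    uniq = sorted(set(tags))
    by_len: dict[int, list] = {}
    for t in uniq:
        by_len.setdefault(len(t), []).append(t)
    db = sorted(mature_db, key=lambda m: m.id)
    offsets = sorted(range(-max_shift, max_shift + 1), key=lambda o: (abs(o), o))
    out: dict[str, KnownHit] = {}
    for L, group in by_len.items():
        mat = np.frombuffer("".join(group).encode(), dtype=np.uint8)
        mat = mat.reshape(len(group), L)
        best_key = np.full((len(group), 3), 2 ** 30, dtype=np.int64)
        best_off = np.zeros(len(group), dtype=np.int64)
        for rank, m in enumerate(db):
            mseq = np.frombuffer(to_dna(m.seq).encode(), dtype=np.uint8)
            M = len(mseq)
            for off in offsets:
                i0, i1 = max(0, -off), min(L, M - off)
                if i1 <= i0:
                    continue
                mm = (mat[:, i0:i1] != mseq[i0 + off:i1 + off]).sum(axis=1)
                mm = mm + (L - (i1 - i0))
                cand = np.stack([mm, np.full(len(group), abs(off)),
                                 np.full(len(group), rank)], axis=1)
                better = (mm <= max_mm) & (
                    (cand[:, 0] < best_key[:, 0])
                    | ((cand[:, 0] == best_key[:, 0])
                       & ((cand[:, 1] < best_key[:, 1])
                          | ((cand[:, 1] == best_key[:, 1])
                             & (cand[:, 2] < best_key[:, 2])))))
                best_key[better] = cand[better]
                best_off[better] = off
        for i, t in enumerate(group):
            if best_key[i, 0] <= max_mm:
                m = db[best_key[i, 2]]
                out[t] = KnownHit(t, m.id, m.family, int(best_key[i, 0]),
                                  int(best_off[i]))
    return out


def match_table(tags, mature_db, max_mm: int = 2, max_shift: int = 2,
                exact_only: bool = False) -> pd.DataFrame:
    """Resolve every tag; exact_only=True restricts to 0 mismatches."""
    if exact_only:
        max_mm = max_shift = 0
    hits = match_known_bulk(tags, mature_db, max_mm=max_mm,
                            max_shift=max_shift)
    rows = [(h.tag, h.mature_id, h.family, h.mismatches, h.offset)
            for t in tags if (h := hits.get(to_dna(t)))]
    return pd.DataFrame(rows, columns=["tag", "mature_id", "family",
                                       "mismatches", "offset"])


def family_counts(hits: pd.DataFrame, counts: pd.DataFrame):
    """Credit tag counts to matures and aggregate to families.

    hits: match_table output; counts: collapse() table. Returns
    (per-mature DataFrame, per-family DataFrame), one count column per
    library. Every tag is credited once, to its single best mature.
    """
    libs = list(counts.columns)
    merged = hits.set_index("tag").join(counts, how="inner")
    per_mature = merged.groupby(["mature_id", "family"])[libs].sum().reset_index()
    per_family = merged.groupby("family")[libs].sum().reset_index()
    return per_mature, per_family


def detection_summary(per_mature: pd.DataFrame, libs=None,
                      high_cut: int = 50) -> pd.DataFrame:
    """Per-library tallies: matures with >=1 read and with more than
    high_cut reads (strict >)."""
    if libs is None:
        libs = [c for c in per_mature.columns
                if c not in ("mature_id", "family")]
    rows = []
    for lib in libs:
        col = per_mature[lib] if lib in per_mature else pd.Series(dtype=int)
        rows.append((lib, int((col >= 1).sum()), int((col > high_cut).sum())))
    return pd.DataFrame(rows, columns=["library", "detected", "above_cut"])
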