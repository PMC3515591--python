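"""Novel miRNA precursor calling from unannotated tag clusters.

Genomic windows around clusters of mapped, unannotated tags are folded
and accepted as precursor candidates when they satisfy MIREAP-style
structural criteria: a single-stemmed hairpin whose most abundant tag
(the putative mature, 18-26 nt) sits entirely on one arm with at least
16 paired bases, a mature/star duplex with at most 4 unpaired mature
bases and 2 nt arm asymmetry, folding energy at or below -18 kcal/mol,
and a precursor length of 70-365 nt. G:U wobbles count as paired.

Rejections carry the first failed criterion, checked in the order
multibranch / arm / pairing / duplex / mfe / length.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from . import fold as _fold
from .io import revcomp, to_dna, to_rna

MFE_MAX = -18.0
PRECURSOR_MIN, PRECURSOR_MAX = 70, 365
MIN_MATURE_PAIRED = 16
MAX_UNPAIRED_MATURE = 4
MAX_DUPLEX_ASYMMETRY = 2


@dataclass(frozen=True)
class PrecursorCandidate:
    id: str
    scaffold: str
    start: int            # 1-based inclusive, forward strand
    end: int
    strand: str
    precursor_seq: str    # RNA, precursor's own strand
    structure: str        # dot-bracket of the precursor
    mfe: float            # kcal/mol
    mature_seq: str       # RNA
    mature_arm: str       # '5p' | '3p'
    star_seq: str
    read_support: int

    @property
    def location(self) -> str:
        return f"{self.scaffold}:{self.start}:{self.end}"


@dataclass(frozen=True)
class Rejection:
    reason: str


def extract_candidate_loci(alignments: pd.DataFrame, scaffold_lengths: dict,
                           flank_up: int = 200, flank_down: int = 200,
                           merge_gap: int = 30) -> pd.DataFrame:
    """Merge nearby tag alignments into candidate windows.

    alignments: map_tags-style table restricted to unannotated tags,
    with a 'count' column (per-tag read support). Windows are cluster
    extents +- flanks, clipped to the scaffold; strand is the
    read-count majority of the cluster.
    """
    if alignments.empty:
        return pd.DataFrame(columns=["scaffold", "start", "end", "strand",
                                     "tags"])
    rows = []
    aligns = alignments.sort_values(["scaffold", "start"], kind="mergesort")
    for scaf, group in aligns.groupby("scaffold"):
        cluster = []
        cl_end = None
        for rec in group.itertuples():
            if cluster and rec.start > cl_end + merge_gap:
                rows.append(_close_cluster(cluster, scaf, flank_up,
                                           flank_down, scaffold_lengths[scaf]))
                cluster = []
            cluster.append(rec)
            cl_end = max(cl_end, rec.end) if cl_end else rec.end
        if cluster:
            rows.append(_close_cluster(cluster, scaf, flank_up, flank_down,
                                       scaffold_lengths[scaf]))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "strand",
                                       "tags"])


def _close_cluster(cluster, scaf, flank_up, flank_down, scaf_len):
    start = min(r.start for r in cluster)
    end = max(r.end for r in cluster)
    support = Counter()
    for r in cluster:
        support[r.strand] += getattr(r, "count", 1)
    strand = "+" if support["+"] >= support["-"] else "-"
    w_start = max(1, start - flank_up)
    w_end = min(scaf_len, end + flank_down)
    tags = [(r.tag, getattr(r, "count", 1), r.start, r.end) for r in cluster]
    return (scaf, w_start, w_end, strand, tags)


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(1 for x, y in zip(a, b) if x != y)


def _stem_is_linear(pairs: dict, lo: int, hi: int) -> bool:
    """True if pairs inside [lo, hi] form one helix chain (allowing
    bulges/internal loops): opening positions sorted ascending must have
    strictly descending partners."""
    opening = sorted(i for i, j in pairs.items()
                     if lo <= i < j <= hi)
    partners = [pairs[i] for i in opening]
    return all(a > b for a, b in zip(partners, partners[1:]))


def call_precursor(window_seq: str, scaffold: str, window_start: int,
                   strand: str, tags, candidate_id: str = "cand",
                   fold_max: int = 400):
    """Evaluate one window; returns PrecursorCandidate or Rejection.

    window_seq: window sequence on the cluster strand (for '-', the
    reverse complement of the forward-strand slice). tags: list of
    (seq, count, genome_start, genome_end) supporting alignments;
    window_start is the window's forward-strand 1-based start.
    """
    window_seq = to_dna(window_seq)
    n = len(window_seq)
    window_end = window_start + n - 1
    # mature = most abundant 18-26 nt tag; ties -> longest, then 5'-most
    usable = []
    for seq, count, g_start, g_end in tags:
        seq = to_dna(seq)
        if not 18 <= len(seq) <= 26:
            continue
        off = (g_start - window_start) if strand == "+" else (window_end - g_end)
        if off < 0 or off + len(seq) > n:
            continue
        # the candidate mature is the genomic sequence under the tag, so
        # tags aligned with mismatches still anchor a locus
        genomic = window_seq[off:off + len(seq)]
        if min(_hamming(genomic, seq), _hamming(genomic, revcomp(seq))) > 2:
            continue
        usable.append((count, len(seq), -off, genomic, off))
    if not usable:
        return Rejection("no_mature")
    usable.sort(reverse=True)
    _count, m_len, _negoff, m_seq, m_off = usable[0]
    read_support = sum(u[0] for u in usable)

    # trim the folding window around the mature
    if n > fold_max:
        half = (fold_max - m_len) // 2
        lo_trim = max(0, m_off - half)
        hi_trim = min(n, lo_trim + fold_max)
        lo_trim = max(0, hi_trim - fold_max)
    else:
        lo_trim, hi_trim = 0, n
    sub = window_seq[lo_trim:hi_trim]
    a = m_off - lo_trim
    b = a + m_len - 1

    result = _fold.fold(sub, max_len=fold_max)
    pairs = result.pairs
    partners = [pairs[i] for i in range(a, b + 1) if i in pairs]
    n_paired = len(partners)
    unpaired = m_len - n_paired

    if n_paired == 0:
        return Rejection("pairing")
    # (b) mature on one arm: no partner inside the mature itself
    star_lo, star_hi = min(partners), max(partners)
    on_one_arm = star_lo > b or star_hi < a
    lo = min(a, star_lo)
    hi = max(b, star_hi)

    # criteria in reporting order
    if not _stem_is_linear(pairs, lo, hi):
        return Rejection("multibranch")
    if not on_one_arm:
        return Rejection("arm")
    if n_paired < MIN_MATURE_PAIRED:
        return Rejection("pairing")
    if unpaired > MAX_UNPAIRED_MATURE:
        return Rejection("duplex_unpaired")
    star_len = star_hi - star_lo + 1
    if abs(star_len - m_len) > MAX_DUPLEX_ASYMMETRY:
        return Rejection("duplex_asymmetry")

    # grow through enclosing lower-stem pairs while the stem stays linear
    while True:
        enclosing = [(i, j) for i, j in pairs.items()
                     if i < j and i < lo and j > hi]
        if not enclosing:
            break
        i, j = max(enclosing)  # innermost enclosing pair
        if _stem_is_linear(pairs, i, j):
            lo, hi = i, j
        else:
            break

    # precursor slice: pad to the length floor
    p_lo, p_hi = lo, hi
    if p_hi - p_lo + 1 < PRECURSOR_MIN:
        pad = PRECURSOR_MIN - (p_hi - p_lo + 1)
        p_lo = max(0, p_lo - (pad + 1) // 2)
        p_hi = min(len(sub) - 1, p_lo + PRECURSOR_MIN - 1)
        p_lo = max(0, p_hi - PRECURSOR_MIN + 1)
    pre_seq = sub[p_lo:p_hi + 1]
    if not PRECURSOR_MIN <= len(pre_seq) <= PRECURSOR_MAX:
        return Rejection("length")
    pre_fold = _fold.fold(pre_seq, max_len=fold_max)
    if pre_fold.mfe > MFE_MAX:
        return Rejection("mfe")

    star_seq = sub[star_lo:star_hi + 1] if n_paired else ""
    arm = "5p" if a < star_lo else "3p"
    # forward-strand genome coordinates of the precursor slice
    w_lo = lo_trim + p_lo
    w_hi = lo_trim + p_hi
    if strand == "+":
        g_start, g_end = window_start + w_lo, window_start + w_hi
    else:
        g_start, g_end = window_end - w_hi, window_end - w_lo
    return PrecursorCandidate(
        id=candidate_id, scaffold=scaffold, start=g_start, end=g_end,
        strand=strand, precursor_seq=to_rna(pre_seq),
        structure=pre_fold.structure, mfe=pre_fold.mfe,
        mature_seq=to_rna(m_seq), mature_arm=arm,
        star_seq=to_rna(star_seq), read_support=read_support)


def first_nt_bias(candidates) -> dict:
    """Composition of the mature 5' first nucleotide over accepted
    candidates; fractions over A/C/G/U summing to 1, or None if empty."""
    firsts = [to_rna(c.mature_seq)[0] for c in candidates]
    if not firsts:
        return None
    n = len(firsts)
    return {b: firsts.count(b) / n for b in "ACGU"}


def candidates_table(candidates) -> pd.DataFrame:
    rows = []
    for c in candidates:
        five = c.mature_seq if c.mature_arm == "5p" else "-"
        three = c.mature_seq if c.mature_arm == "3p" else "-"
        rows.append((c.id, five, three, len(c.mature_seq),
                     len(c.precursor_seq), c.read_support, c.location,
                     c.strand, c.mfe))
    return pd.DataFrame(rows, columns=[
        "id", "seq_5p", "seq_3p", "mature_length", "precursor_length",
        "count", "location", "strand", "mfe"])


def write_gff3(candidates, path) -> None:
    """Precursor + mature features, 1-based inclusive, GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in candidates:
            fh.write(f"{c.scaffold}\tmirseq\tmiRNA_primary_transcript\t"
                     f"{c.start}\t{c.end}\t.\t{c.strand}\t.\t"
                     f"ID={c.id};mfe={c.mfe}\n")
            m_rel = to_dna(c.precursor_seq).find(to_dna(c.mature_seq))
            if m_rel >= 0:
                if c.strand == "+":
                    ms = c.start + m_rel
                else:
                    ms = c.end - m_rel - len(c.mature_seq) + 1
                me = ms + len(c.mature_seq) - 1
                fh.write(f"{c.scaffold}\tmirseq\tmiRNA\t{ms}\t{me}\t.\t"
                         f"{c.strand}\t.\tID={c.id}_mature;Parent={c.id}\n")
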