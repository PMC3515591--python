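"""Read cleaning, tag collapsing and length statistics.

Raw reads pass four gates, in order: quality (mean Phred and N count),
3' adapter detection and removal, trailing poly-A stripping, and the
18-30 nt length window. Reads without a detectable 3' adapter are
discarded: for a size-selected small RNA library an undetected adapter
means the insert ran past the read, so the full insert was not
sequenced. Sequences are normalized to the DNA alphabet internally;
RNA (U) input is accepted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import read_fastq, to_dna


class FastqFormatError(ValueError):
    pass


@dataclass
class LibraryStats:
    """Read-accounting ledger for one library."""
    raw_reads: int = 0
    high_quality_reads: int = 0
    clean_reads: int = 0
    unique_tags: int = 0
    mapped_total: int = 0
    mapped_unique: int = 0
    removed: dict = field(default_factory=dict)   # reason -> count

    def validate(self) -> None:
        assert self.raw_reads >= self.high_quality_reads >= self.clean_reads
        assert self.unique_tags <= self.clean_reads
        assert self.mapped_total <= self.clean_reads
        assert self.mapped_unique <= self.unique_tags
        assert self.raw_reads == self.clean_reads + sum(self.removed.values())

    def as_dict(self) -> dict:
        return {"raw_reads": self.raw_reads,
                "high_quality_reads": self.high_quality_reads,
                "clean_reads": self.clean_reads,
                "unique_tags": self.unique_tags,
                "mapped_total": self.mapped_total,
                "mapped_unique": self.mapped_unique,
                "removed": dict(self.removed)}


def trim_adapter(read: str, adapter3: str, min_overlap: int = 6):
    """Remove the 3' adapter; return the insert, or None if no adapter.

    The leftmost position whose suffix matches a prefix of the adapter
    (>= min_overlap nt, <= 1 mismatch per 10 nt of overlap) wins, which
    yields the longest adapter match. An adapter starting at position 0
    (empty insert) returns the empty string; the caller discards it at
    the length gate.
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    read = to_dna(read)
    adapter3 = to_dna(adapter3)
    n = len(read)
    for p in range(0, n - min_overlap + 1):
        overlap = min(len(adapter3), n - p)
        allowed = overlap // 10
        mm = 0
        ok = True
        for a, b in zip(read[p:p + overlap], adapter3[:overlap]):
            if a != b:
                mm += 1
                if mm > allowed:
                    ok = False
                    break
        if ok:
            return read[:p]
    return None


def strip_polya(seq: str, min_run: int = 6) -> str:
    """Remove a trailing run of >= min_run A's."""
    n = len(seq)
    k = n
    while k > 0 and seq[k - 1] == "A":
        k -= 1
    return seq[:k] if n - k >= min_run else seq


def clean_reads(fastq, adapter3: str, min_len: int = 18, max_len: int = 30,
                mean_q: float = 20.0, max_n: int = 1,
                do_strip_polya: bool = True):
    """Clean one library.

    fastq: a path to a FASTQ file or an iterable of
    (id, seq, qualities) records. Returns (clean sequence list,
    LibraryStats with the removal ledger populated).
    """
    records = read_fastq(fastq) if isinstance(fastq, (str, bytes)) or hasattr(fastq, "__fspath__") else fastq
    stats = LibraryStats()
    removed = Counter()
    clean = []
    for idx, rec in enumerate(records):
        try:
            rid, seq, quals = rec
            seq = to_dna(seq)
            if len(seq) != len(quals):
                raise ValueError("length mismatch")
        except (TypeError, ValueError) as exc:
            raise FastqFormatError(f"malformed FASTQ record {idx}: {exc}") from exc
        stats.raw_reads += 1
        if (np.mean(quals) < mean_q if quals else True) or seq.count("N") > max_n:
            removed["low_quality"] += 1
            continue
        stats.high_quality_reads += 1
        insert = trim_adapter(seq, adapter3)
        if insert is None:
            removed["no_adapter"] += 1
            continue
        if do_strip_polya:
            insert = strip_polya(insert)
        if len(insert) < min_len:
            removed["too_short"] += 1
            continue
        if len(insert) > max_len:
            removed["too_long"] += 1
            continue
        clean.append(insert)
        stats.clean_reads += 1
    stats.removed = dict(removed)
    stats.unique_tags = len(set(clean))
    stats.validate()
    return clean, stats


def collapse(clean_by_library: dict) -> pd.DataFrame:
    """Collapse clean reads to unique tags with per-library counts.

    clean_by_library: library name -> list of clean sequences.
    Returns a DataFrame indexed by tag sequence, one count column per
    library; permutation-invariant and idempotent by construction.
    """
    libs = sorted(clean_by_library)
    counters = {lib: Counter(clean_by_library[lib]) for lib in libs}
    tags = sorted(set().union(*[c.keys() for c in counters.values()]) if libs else [])
    table = pd.DataFrame(
        {lib: [counters[lib].get(t, 0) for t in tags] for lib in libs},
        index=pd.Index(tags, name="tag"), dtype=np.int64)
    return table


def length_distribution(tags: pd.DataFrame, by: str = "unique"):
    """Histogram of tag lengths.

    by='unique' weights each distinct tag once; by='total' weights by
    summed read counts. Returns (Series of frequencies summing to 1,
    modal length or None for an empty table).
    """
    if by not in ("unique", "total"):
        raise ValueError("by must be 'unique' or 'total'")
    if tags.empty:
        return pd.Series(dtype=float), None
    lengths = tags.index.str.len()
    w = np.ones(len(tags)) if by == "unique" else tags.sum(axis=1).to_numpy(float)
    hist = pd.Series(w).groupby(np.asarray(lengths)).sum()
    hist = hist / hist.sum()
    return hist, int(hist.idxmax())
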