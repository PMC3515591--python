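"""Genome mapping and category assignment for unique tags.

Mapping is ungapped with a bounded number of substitutions (SOAP2-like
behaviour) on both strands, via a pigeonhole seed index: any alignment
with <= k mismatches contains at least one exact match among k+1 tag
chunks, so candidate loci come from exact chunk lookups and are then
verified base by base.

Each tag receives exactly one category with the fixed priority
rRNA > tRNA > snRNA > snoRNA > miRNA > exon-sense > exon-antisense >
intron-sense > intron-antisense > unannotated, so categories partition
the tag set and 'unannotated' is the residual class.
"""

from __future__ import annotations

from collections import defaultdict

import pandas as pd

from .io import revcomp, to_dna
from . import known as _known

CATEGORY_PRIORITY = ["rRNA", "tRNA", "snRNA", "snoRNA", "miRNA",
                     "exon_sense", "exon_antisense",
                     "intron_sense", "intron_antisense", "unannotated"]


class AnnotationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Exact k-mer position index over a set of scaffolds, built lazily
    per requested k."""

    def __init__(self, genome: dict):
        self.genome = {k: to_dna(v) for k, v in genome.items()}
        self._kmer: dict[int, dict] = {}

    def positions(self, kmer: str):
        k = len(kmer)
        if k not in self._kmer:
            idx = defaultdict(list)
            for scaf in sorted(self.genome):
                seq = self.genome[scaf]
                for i in range(len(seq) - k + 1):
                    idx[seq[i:i + k]].append((scaf, i))
            self._kmer[k] = dict(idx)
        return self._kmer[k].get(kmer, ())


def _chunks(tag: str, parts: int):
    """Split into `parts` near-equal chunks; yields (offset, chunk)."""
    L = len(tag)
    base = L // parts
    off = 0
    for p in range(parts):
        size = base + (1 if p < L % parts else 0)
        yield off, tag[off:off + size]
        off += size


def _mismatches(a: str, b: str, cap: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > cap:
                return mm
    return mm


def map_tags(tags, genome: dict, max_mismatch: int = 2) -> pd.DataFrame:
    """All ungapped alignments of each tag with <= max_mismatch
    substitutions, both strands.

    Returns a DataFrame (tag, scaffold, start, end, strand, mismatches)
    with 1-based inclusive forward-strand coordinates, sorted by
    (tag, scaffold, start, strand).
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    rows = []
    for tag in tags:
        tag_dna = to_dna(tag)
        L = len(tag_dna)
        seen = set()
        for strand, query in (("+", tag_dna), ("-", revcomp(tag_dna))):
            for off, chunk in _chunks(query, max_mismatch + 1):
                for scaf, pos in index.positions(chunk):
                    start0 = pos - off
                    if start0 < 0 or start0 + L > len(index.genome[scaf]):
                        continue
                    key = (scaf, start0, strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    window = index.genome[scaf][start0:start0 + L]
                    mm = _mismatches(query, window, max_mismatch)
                    if mm <= max_mismatch:
                        rows.append((tag, scaf, start0 + 1, start0 + L,
                                     strand, mm))
    df = pd.DataFrame(rows, columns=["tag", "scaffold", "start", "end",
                                     "strand", "mismatches"])
    return df.sort_values(["tag", "scaffold", "start", "strand"],
                          kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# categorization
# ---------------------------------------------------------------------------

def _validate_annotation(gene_annot: pd.DataFrame) -> None:
    need = {"scaffold", "start", "end", "strand", "feature", "gene_id"}
    if not need.issubset(gene_annot.columns):
        raise AnnotationError(f"annotation needs columns {sorted(need)}")
    bad = gene_annot[(gene_annot.start > gene_annot.end)
                     | (gene_annot.start < 1)
                     | ~gene_annot.feature.isin(["exon", "intron"])
                     | ~gene_annot.strand.isin(["+", "-"])]
    if len(bad):
        raise AnnotationError(f"{len(bad)} invalid annotation intervals")


def _ncrna_substring_index(ncrna_refs: dict, lengths) -> list:
    """Per category, the set of all reference substrings at the tag
    lengths in play; containment then becomes one set lookup per tag."""
    index = []
    for cat in ("rRNA", "tRNA", "snRNA", "snoRNA"):
        subs = set()
        for _rid, rseq in ncrna_refs.get(cat, ()):
            rseq = to_dna(rseq)
            for L in lengths:
                for i in range(len(rseq) - L + 1):
                    subs.add(rseq[i:i + L])
        index.append((cat, subs))
    return index


def categorize(tags, alignments: pd.DataFrame, ncrna_refs: dict,
               gene_annot: pd.DataFrame, mature_db,
               max_mm_mirna: int = 2) -> pd.DataFrame:
    """Assign every tag exactly one category.

    tags: iterable of tag sequences; alignments: output of map_tags;
    mature_db: list of MatureMiRNA (see known module). Gene overlap uses
    the best (fewest-mismatch) alignments; among those, the category is
    the highest-priority one, ties broken by leftmost coordinate.
    """
    _validate_annotation(gene_annot)
    tags = [to_dna(t) for t in tags]
    nc_index = _ncrna_substring_index(ncrna_refs, sorted({len(t) for t in tags}))
    known_hits = (_known.match_known_bulk(tags, mature_db,
                                          max_mm=max_mm_mirna)
                  if mature_db else {})
    by_tag: dict[str, list] = {}
    for a in alignments.itertuples():
        by_tag.setdefault(a.tag, []).append(a)
    feats_by_scaf: dict[str, list] = {}
    for f in gene_annot.itertuples():
        feats_by_scaf.setdefault(f.scaffold, []).append(
            (f.start, f.end, f.strand, f.feature, f.gene_id))
    rows = []
    for tag_dna in tags:
        cat, evidence = None, ""
        rc = revcomp(tag_dna)
        for nc_cat, subs in nc_index:
            if tag_dna in subs or rc in subs:
                cat, evidence = nc_cat, "reference_match"
                break
        if cat is None and tag_dna in known_hits:
            cat, evidence = "miRNA", known_hits[tag_dna].mature_id
        if cat is None and tag_dna in by_tag:
            aligns = by_tag[tag_dna]
            best_mm = min(a.mismatches for a in aligns)
            candidates = []
            for a in aligns:
                if a.mismatches != best_mm:
                    continue
                for fs, fe, fstrand, feat, gid in feats_by_scaf.get(a.scaffold, ()):
                    if fs <= a.end and fe >= a.start:
                        sense = "sense" if fstrand == a.strand else "antisense"
                        candidates.append((f"{feat}_{sense}", a.start, gid))
            if candidates:
                candidates.sort(key=lambda c: (CATEGORY_PRIORITY.index(c[0]), c[1]))
                cat, evidence = candidates[0][0], candidates[0][2]
        if cat is None:
            cat, evidence = "unannotated", ""
        rows.append((tag_dna, cat, evidence))
    return pd.DataFrame(rows, columns=["tag", "category", "evidence"])


def summarize_categories(assignments: pd.DataFrame,
                         counts: pd.DataFrame) -> pd.DataFrame:
    """Per-library unique/total counts and percentages per category.

    counts: collapse() table (index tag, one column per library).
    Returns a table with one row per category and, per library, columns
    <lib>_unique, <lib>_unique_pct, <lib>_total, <lib>_total_pct.
    """
    merged = counts.join(assignments.set_index("tag")["category"], how="left")
    merged["category"] = merged["category"].fillna("unannotated")
    out = pd.DataFrame(index=pd.Index(CATEGORY_PRIORITY, name="category"))
    for lib in counts.columns:
        present = merged[merged[lib] > 0]
        uniq = present.groupby("category").size()
        tot = present.groupby("category")[lib].sum()
        out[f"{lib}_unique"] = uniq.reindex(CATEGORY_PRIORITY).fillna(0).astype(int)
        out[f"{lib}_total"] = tot.reindex(CATEGORY_PRIORITY).fillna(0).astype(int)
        u_sum, t_sum = out[f"{lib}_unique"].sum(), out[f"{lib}_total"].sum()
        out[f"{lib}_unique_pct"] = 100.0 * out[f"{lib}_unique"] / max(u_sum, 1)
        out[f"{lib}_total_pct"] = 100.0 * out[f"{lib}_total"] / max(t_sum, 1)
    return out.reset_index()
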