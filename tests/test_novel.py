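"""Novel precursor calling: window extraction, hairpin criteria,
generator-oracle recall and first-nucleotide bias."""

import numpy as np
import pandas as pd
import pytest

from mirseq import novel, simulate
from mirseq.io import revcomp, to_dna, to_rna
from mirseq.novel import (PrecursorCandidate, Rejection, call_precursor,
                          extract_candidate_loci, first_nt_bias)


def _aligns(rows):
    df = pd.DataFrame(rows, columns=["tag", "scaffold", "start", "end",
                                     "strand", "mismatches"])
    df["count"] = 1
    return df


class TestExtractLoci:
    def test_single_tag_window_arithmetic(self):
        df = _aligns([("T" * 21, "s1", 1000, 1020, "+", 0)])
        w = extract_candidate_loci(df, {"s1": 10_000})
        assert (w.start.iloc[0], w.end.iloc[0]) == (800, 1220)

    def test_nearby_tags_merged(self):
        df = _aligns([("A" * 21, "s1", 1000, 1020, "+", 0),
                      ("C" * 21, "s1", 1030, 1050, "+", 0)])
        w = extract_candidate_loci(df, {"s1": 10_000})
        assert len(w) == 1
        assert (w.start.iloc[0], w.end.iloc[0]) == (800, 1250)

    def test_distant_tags_split(self):
        df = _aligns([("A" * 21, "s1", 1000, 1020, "+", 0),
                      ("C" * 21, "s1", 2000, 2020, "+", 0)])
        assert len(extract_candidate_loci(df, {"s1": 10_000})) == 2

    def test_clipped_at_scaffold_bounds(self):
        df = _aligns([("A" * 21, "s1", 10, 30, "+", 0)])
        w = extract_candidate_loci(df, {"s1": 150})
        assert w.start.iloc[0] == 1
        assert w.end.iloc[0] == 150

    def test_empty(self):
        assert extract_candidate_loci(_aligns([]), {}).empty


def _window_for(planted, genome, flank=120):
    """Window around a planted locus plus the mature tag support."""
    p = planted
    glen = len(genome[p.scaffold])
    w_start = max(1, p.start - flank)
    w_end = min(glen, p.end + flank)
    seq = genome[p.scaffold][w_start - 1:w_end]
    if p.strand == "-":
        seq = revcomp(seq)
    scaf, ms, me = simulate.mature_locus(p)
    tags = [(to_dna(p.mature_seq), 25, ms, me)]
    return seq, w_start, tags


class TestCallPrecursor:
    def test_planted_hairpins_accepted(self, study):
        """Generator-oracle: every planted locus is called, the reported
        mature equals the planted mature, and the locus covers it."""
        for p in study["planted"]:
            seq, w_start, tags = _window_for(p, study["genome"])
            res = call_precursor(seq, p.scaffold, w_start, p.strand, tags,
                                 candidate_id=p.id)
            assert isinstance(res, PrecursorCandidate), (p.id, res)
            assert to_dna(res.mature_seq) == to_dna(p.mature_seq)
            assert res.strand == p.strand
            # called locus overlaps the planted precursor and contains
            # the mature/star duplex
            assert res.start <= p.end and res.end >= p.start
            scaf, ms, me = simulate.mature_locus(p)
            assert res.start <= ms and res.end >= me
            assert 70 <= len(res.precursor_seq) <= 365
            assert res.mfe <= -18.0
            assert to_dna(res.mature_seq) in to_dna(res.precursor_seq)

    def test_no_supporting_tag(self):
        res = call_precursor("ACGT" * 50, "s1", 1, "+", [])
        assert res == Rejection("no_mature")

    def test_69nt_window_rejected_on_length_floor(self):
        """A perfect hairpin confined to a 69 nt window cannot reach the
        70 nt precursor floor."""
        mature = "TGACAGAAGAGAGTGAGCACG"          # 21 nt
        star = revcomp(mature)
        window = "CGATCGATC" + mature + "GAAACAAA" + star + "TTCAGGTCAG"
        assert len(window) == 69
        tags = [(mature, 10, 101 + 9, 101 + 9 + 20)]
        res = call_precursor(window, "s1", 101, "+", tags)
        assert res == Rejection("length")

    def test_random_windows_mostly_rejected(self):
        """Random sequence with a single supporting tag should almost
        never satisfy the hairpin criteria."""
        rng = np.random.default_rng(123)
        accepted = 0
        n = 25
        for _ in range(n):
            w = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
            s0 = int(rng.integers(100, 180))
            tags = [(w[s0:s0 + 21], 10, s0 + 1, s0 + 21)]
            res = call_precursor(w, "s1", 1, "+", tags)
            accepted += isinstance(res, PrecursorCandidate)
        assert accepted <= 1

    def test_accepted_candidates_satisfy_criteria_when_rechecked(self, study):
        """Independent re-validation of every reported candidate."""
        from mirseq import fold
        for p in study["planted"][:5]:
            seq, w_start, tags = _window_for(p, study["genome"])
            res = call_precursor(seq, p.scaffold, w_start, p.strand, tags)
            assert isinstance(res, PrecursorCandidate)
            r = fold.fold(to_dna(res.precursor_seq))
            assert r.mfe <= -18.0
            pre = to_dna(res.precursor_seq)
            m = pre.find(to_dna(res.mature_seq))
            span = range(m, m + len(res.mature_seq))
            partners = [r.pairs[i] for i in span if i in r.pairs]
            assert len(partners) >= 16
            assert all(j not in span for j in partners)


class TestFirstNtBias:
    def _cand(self, mature):
        return PrecursorCandidate("c", "s", 1, 100, "+", "A" * 100, "." * 100,
                                  -20.0, mature, "5p", "", 1)

    def test_all_u(self):
        bias = first_nt_bias([self._cand("UACG" * 5 + "U")])
        assert bias["U"] == 1.0

    def test_mixed_fractions(self):
        cands = [self._cand("U" + "ACG" * 7)] * 47 + \
                [self._cand("A" + "ACG" * 7)] * 53
        bias = first_nt_bias(cands)
        assert bias["U"] == pytest.approx(0.47)
        assert sum(bias.values()) == pytest.approx(1.0)

    def test_empty(self):
        assert first_nt_bias([]) is None

    def test_generated_matures_lean_u(self):
        """The generator biases mature first nucleotides toward U,
        mirroring real plant miRNA composition."""
        rng = np.random.default_rng(17)
        matures = [simulate._make_hairpin(rng)[0] for _ in range(100)]
        bias = first_nt_bias([self._cand(m) for m in matures])
        assert bias["U"] == max(bias.values())
        assert bias["U"] >= 0.35
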