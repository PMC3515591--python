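"""Known-miRNA matching and count aggregation."""

import random

import pandas as pd
import pytest

from mirseq import datasets
from mirseq.known import (KnownHit, MatureMiRNA, detection_summary,
                          family_counts, match_known, match_known_bulk,
                          match_table)
from mirseq.preprocess import collapse


@pytest.fixture(scope="module")
def peach_db():
    df = datasets.peach_conserved_mirnas()
    return [MatureMiRNA(fam, fam, row.sequence)
            for fam, row in df.iterrows()]


def _brute_force(tag, db, max_mm=2, max_shift=2):
    """Oracle: exhaustive comparison over every mature and offset."""
    best = None
    for m in db:
        mseq = m.seq.replace("U", "T")
        t = tag.replace("U", "T")
        for off in range(-max_shift, max_shift + 1):
            mm = 0
            for i in range(len(t)):
                j = i + off
                if 0 <= j < len(mseq):
                    mm += t[i] != mseq[j]
                else:
                    mm += 1
            if mm <= max_mm:
                key = (mm, abs(off), m.id)
                if best is None or key < best[0]:
                    best = (key, (m.id, mm, off))
    return best[1] if best else None


def test_mir156_exact_hit(peach_db):
    hit = match_known("UGACAGAAGAGAGUGAGCAC", peach_db)
    assert hit.mature_id == "miR156"
    assert hit.mismatches == 0
    assert hit.offset == 0


def test_three_substitutions_miss(peach_db):
    tag = "UGACAGAAGAGAGUGAGCAC"
    mutated = "ACU" + tag[3:]  # 3 substitutions vs miR156
    hit = match_known(mutated, peach_db)
    assert hit is None or hit.mismatches <= 2  # may hit another entry
    assert _brute_force(mutated, peach_db) == (
        (hit.mature_id, hit.mismatches, hit.offset) if hit else None)


def test_random_tags_match_brute_force(peach_db):
    rnd = random.Random(2)
    db10 = peach_db[:10]
    for _ in range(80):
        if rnd.random() < 0.5:
            tag = "".join(rnd.choice("ACGU") for _ in range(21))
        else:  # perturbed real mature: exercises hits
            base = rnd.choice(db10).seq
            t = list(base)
            for _ in range(rnd.randint(0, 3)):
                i = rnd.randrange(len(t))
                t[i] = rnd.choice("ACGU")
            tag = "".join(t)
        got = match_known(tag, db10)
        expect = _brute_force(tag, db10)
        assert (None if got is None
                else (got.mature_id, got.mismatches, got.offset)) == expect


def test_bulk_matches_scalar(peach_db):
    rnd = random.Random(4)
    tags = []
    for _ in range(60):
        base = rnd.choice(peach_db).seq
        t = list(base)
        for _ in range(rnd.randint(0, 3)):
            t[rnd.randrange(len(t))] = rnd.choice("ACGU")
        tags.append("".join(t).replace("U", "T"))
    bulk = match_known_bulk(tags, peach_db)
    for tag in tags:
        scalar = match_known(tag, peach_db)
        if scalar is None:
            assert tag not in bulk
        else:
            h = bulk[tag]
            assert (h.mature_id, h.mismatches, h.offset) == \
                (scalar.mature_id, scalar.mismatches, scalar.offset)


def test_isomir_offset_detected(peach_db):
    tag = "ACAGAAGAGAGUGAGCACAA"  # miR156 shifted 5' by +2, 3' extended
    hit = match_known(tag, peach_db)
    assert hit.mature_id == "miR156"
    assert hit.offset == 2


class TestFamilyCounts:
    def test_single_credit(self):
        counts = collapse({"LC": ["A" * 20] * 10})
        hits = pd.DataFrame([("A" * 20, "m1", "famA", 0, 0)],
                            columns=["tag", "mature_id", "family",
                                     "mismatches", "offset"])
        per_mature, per_family = family_counts(hits, counts)
        assert per_family.set_index("family").loc["famA", "LC"] == 10

    def test_two_members_sum(self):
        counts = collapse({"LC": ["A" * 20] * 3 + ["C" * 20] * 4})
        hits = pd.DataFrame([("A" * 20, "m1", "famA", 0, 0),
                             ("C" * 20, "m2", "famA", 1, 0)],
                            columns=["tag", "mature_id", "family",
                                     "mismatches", "offset"])
        _, per_family = family_counts(hits, counts)
        assert per_family.set_index("family").loc["famA", "LC"] == 7

    def test_credit_conservation_on_synthetic(self, study, libraries):
        """Recovered counts equal designed sampling exactly: planted
        matures are sequenced verbatim, so per-mature totals equal the
        truth table counts."""
        from mirseq.preprocess import clean_reads
        from mirseq import simulate
        truth = libraries["truth"]
        clean = {}
        for lib in ("LC", "LS", "RC", "RS"):
            clean[lib], _ = clean_reads(iter(libraries["reads"][lib]),
                                        simulate.ADAPTER3_DEFAULT)
        counts = collapse(clean)
        db = [MatureMiRNA(p.id, p.id, p.mature_seq)
              for p in study["planted"]]
        hits = match_table(counts.index, db, max_mm=0, max_shift=0)
        per_mature, _ = family_counts(hits, counts)
        merged = per_mature.set_index("mature_id").join(
            truth.set_index("mirna_id"), how="right")
        for lib in ("LC", "LS", "RC", "RS"):
            got = merged[lib].fillna(0)
            want = merged[f"count_{lib}"]
            # exact-match credit recovers at least the designed reads;
            # contaminant collisions are the only possible excess
            assert (got >= want).all()
            assert (got - want).sum() <= 0.01 * want.sum()


class TestDetectionSummary:
    def _table(self, counts):
        return pd.DataFrame({"mature_id": [f"m{i}" for i in range(len(counts))],
                             "family": "f", "LC": counts})

    def test_all_zero(self):
        out = detection_summary(self._table([0, 0]), libs=["LC"])
        assert out.detected.iloc[0] == 0
        assert out.above_cut.iloc[0] == 0

    def test_strict_threshold(self):
        out = detection_summary(self._table([60, 50, 1]), libs=["LC"])
        assert out.detected.iloc[0] == 3
        assert out.above_cut.iloc[0] == 1  # strict > 50

    def test_row_order_invariant(self):
        a = detection_summary(self._table([60, 50, 1]), libs=["LC"])
        b = detection_summary(self._table([1, 60, 50]), libs=["LC"])
        assert a.equals(b)
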