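"""Target-site alignment and the five acceptance rules."""

import random

import pytest

from mirseq import reference, simulate
from mirseq.io import revcomp, to_rna
from mirseq.simulate import ConfigurationError, make_transcriptome
from mirseq.targets import (TargetAlignment, accept, align_site,
                            scan_transcripts)

MIR = "UGACAGAAGAGAGUGAGCACG"  # 21 nt


def _site(mirna):
    """Perfect target site: reverse complement, RNA alphabet."""
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return "".join(comp[c] for c in mirna[::-1])


class TestAlignSite:
    def test_perfect_complement_all_match(self):
        ali = align_site(MIR, _site(MIR))
        assert set(ali.states) == {"m"}
        assert ali.weighted_mismatches == 0.0

    def test_single_wobble_scores_half(self):
        site = list(_site(MIR))
        # miRNA position 3 is A->no wobble; use position 1 (U): U:G wobble
        assert MIR[0] == "U"
        site[len(MIR) - 1] = "G"
        ali = align_site(MIR, "".join(site))
        assert ali.states[0] == "w"
        assert ali.weighted_mismatches == 0.5

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            align_site(MIR, _site(MIR)[:-1])

    def test_states_equal_per_base_oracle(self):
        """Each position independently re-derived from a pairing table."""
        wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
        wob = {("G", "U"), ("U", "G")}
        rnd = random.Random(6)
        for _ in range(50):
            m = "".join(rnd.choice("ACGU") for _ in range(21))
            w = "".join(rnd.choice("ACGU") for _ in range(21))
            ali = align_site(m, w)
            for i in range(21):
                pair = (m[i], w[21 - 1 - i])
                expect = "m" if pair in wc else "w" if pair in wob else "x"
                assert ali.states[i] == expect

    def test_dna_input_accepted(self):
        ali = align_site(MIR.replace("U", "T"), _site(MIR).replace("U", "T"))
        assert set(ali.states) == {"m"}


def _ali(states):
    return TargetAlignment("m", "t", 1, len(states), tuple(states))


class TestAccept:
    def test_perfect(self):
        assert accept(_ali("m" * 21)) == (True, None)

    def test_mismatch_at_position_10_rejected(self):
        states = ["m"] * 21
        states[9] = "x"
        assert accept(_ali(states)) == (False, "iv")

    def test_four_scattered_mismatches_accepted(self):
        states = ["m"] * 21
        for p in (13, 15, 17, 20):   # outside 2-12, none adjacent
            states[p - 1] = "x"
        assert accept(_ali(states)) == (True, None)

    def test_five_mismatches_rejected_total(self):
        states = ["m"] * 21
        for p in (1, 13, 15, 17, 20):
            states[p - 1] = "x"
        assert accept(_ali(states)) == (False, "i")

    def test_three_adjacent_rejected(self):
        states = ["m"] * 21
        for p in (14, 15, 16):
            states[p - 1] = "x"
        assert accept(_ali(states)) == (False, "ii")

    def test_adjacent_in_seed_rejected(self):
        states = ["m"] * 21
        states[2] = states[3] = "x"
        assert accept(_ali(states)) == (False, "iii")

    def test_seed_weighted_cap(self):
        states = ["m"] * 21
        # 2 mismatches + 2 wobbles in 1-12 = 3.0 > 2.5, none adjacent,
        # none at 10-11
        states[0] = states[4] = "x"
        states[6] = states[8] = "w"
        assert accept(_ali(states)) == (False, "v")

    def test_wobbles_do_not_trigger_positional_rules_by_default(self):
        states = ["m"] * 21
        states[9] = "w"          # wobble at position 10
        states[2] = states[3] = "w"  # adjacent wobbles in seed
        assert accept(_ali(states)) == (True, None)
        assert accept(_ali(states), strict_wobble=True)[0] is False

    @pytest.mark.parametrize("L", [20, 21, 22])
    def test_rule_engine_matches_direct_evaluation(self, L):
        """300 random state vectors per length vs the criteria re-checked
        one clause at a time."""
        rnd = random.Random(100 + L)
        for _ in range(300):
            states = rnd.choices("mwx", weights=[8, 1, 2], k=L)
            ok, _why = accept(_ali(states))
            assert ok == reference.target_rules_direct(states)

    def test_monotone_weight_under_added_mismatch(self):
        states = ["m"] * 21
        base = _ali(states)
        for i in range(21):
            worse = list(states)
            worse[i] = "x"
            assert _ali(worse).weighted_mismatches > base.weighted_mismatches


class TestScan:
    def test_single_planted_perfect_site(self):
        rnd = random.Random(8)
        body = "".join(rnd.choice("ACGT") for _ in range(400))
        site = _site(MIR).replace("U", "T")
        tr = {"t1": body[:100] + site + body[100:]}
        hits = scan_transcripts({"mir1": MIR}, tr)
        exact = hits[hits.weighted_mismatches == 0]
        assert len(exact) == 1
        assert (exact.start.iloc[0], exact.end.iloc[0]) == (101, 121)

    def test_empty_transcript_set(self):
        assert scan_transcripts({"mir1": MIR}, {}).empty

    def test_synthetic_truth_table(self, study):
        """Planted sites with accept-able plans are recovered exactly;
        the planned state vectors are reproduced verbatim."""
        planted = study["planted"][:6]
        plan = [
            (planted[0].id, []),
            (planted[1].id, [(14, "x"), (17, "x")]),
            (planted[2].id, [(10, "x")]),            # must be rejected
            (planted[3].id, [(1, "x"), (13, "x")]),
        ]
        transcripts, truth = make_transcriptome(planted, plan, seed=77)
        mirnas = {p.id: to_rna(p.mature_seq) for p in planted}
        hits = scan_transcripts(mirnas, transcripts)
        for row in truth.itertuples():
            sub = hits[(hits.mirna_id == row.mirna_id)
                       & (hits.transcript_id == row.transcript_id)
                       & (hits.start == row.site_start)]
            should_accept = reference.target_rules_direct(row.states)
            assert len(sub) == (1 if should_accept else 0)
        # no hits on decoy transcripts at this stringency
        decoys = hits[hits.transcript_id.str.startswith("decoy")]
        assert len(decoys) == 0


class TestTranscriptomePlans:
    def test_zero_mismatch_site_is_reverse_complement(self, study):
        p = study["planted"][0]
        transcripts, truth = make_transcriptome([p], [(p.id, [])], seed=5)
        row = truth.iloc[0]
        site = transcripts[row.transcript_id][row.site_start - 1:row.site_end]
        assert site == revcomp(p.mature_seq.replace("U", "T"))

    def test_planned_states_reproduced_by_aligner(self, study):
        p = study["planted"][1]
        mature = to_rna(p.mature_seq)
        wob_pos = next(i + 1 for i, c in enumerate(mature)
                       if c in "GU" and i + 1 not in (10, 11))
        plan = [(p.id, [(wob_pos, "w"), (14, "x")])]
        transcripts, truth = make_transcriptome([p], plan, seed=6)
        row = truth.iloc[0]
        window = transcripts[row.transcript_id][row.site_start - 1:row.site_end]
        ali = align_site(mature, window)
        assert "".join(ali.states) == row.states

    def test_invalid_position_raises(self, study):
        p = study["planted"][0]
        with pytest.raises(ConfigurationError):
            make_transcriptome([p], [(p.id, [(99, "x")])], seed=1)

    def test_wobble_at_non_gu_base_raises(self, study):
        p = study["planted"][0]
        mature = to_rna(p.mature_seq)
        bad = next((i + 1 for i, c in enumerate(mature) if c in "AC"), None)
        if bad is None:
            pytest.skip("mature has no A/C positions")
        with pytest.raises(ConfigurationError):
            make_transcriptome([p], [(p.id, [(bad, "w")])], seed=1)
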