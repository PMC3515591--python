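"""Synthetic-data generator: construction invariants, determinism,
degenerate mixtures and designed-effect recovery."""

import numpy as np
import pytest

from conftest import small_design
from mirseq import simulate
from mirseq.io import revcomp, to_dna
from mirseq.simulate import (ConfigurationError, LibrarySpec,
                             SimulationDesign, generate_genome,
                             make_transcriptome, mature_locus,
                             plant_hairpins, simulate_libraries)


class TestGenome:
    def test_empty_design(self):
        d = small_design()
        d.n_scaffolds = 0
        assert generate_genome(d) == {}

    def test_deterministic_under_seed(self):
        a = generate_genome(small_design(seed=7))
        b = generate_genome(small_design(seed=7))
        assert a == b

    def test_construction(self):
        d = small_design()
        d.n_scaffolds, d.scaffold_length = 2, 50_000
        g = generate_genome(d)
        assert sorted(g) == ["scaffold_1", "scaffold_2"]
        assert all(len(s) == 50_000 for s in g.values())
        assert all(set(s) <= set("ACGT") for s in g.values())

    def test_invalid_config(self):
        d = small_design()
        d.scaffold_length = -5
        with pytest.raises(ConfigurationError):
            generate_genome(d)


class TestPlantHairpins:
    def test_precursor_written_at_coordinates(self, study):
        for p in study["planted"]:
            slice_ = study["genome"][p.scaffold][p.start - 1:p.end]
            expected = to_dna(p.precursor_seq)
            if p.strand == "-":
                expected = revcomp(expected)
            assert slice_ == expected

    def test_mature_inside_precursor_and_length_bounds(self, study):
        for p in study["planted"]:
            assert to_dna(p.mature_seq) in to_dna(p.precursor_seq)
            assert 70 <= len(p.precursor_seq) <= 365
            assert 18 <= len(p.mature_seq) <= 26

    def test_star_is_near_reverse_complement(self, study):
        for p in study["planted"]:
            rc = revcomp(to_dna(p.mature_seq))
            star = to_dna(p.star_seq)
            mm = sum(a != b for a, b in zip(rc, star))
            assert mm <= 4

    def test_loci_non_overlapping(self, study):
        seen = []
        for p in study["planted"]:
            for scaf, s, e in seen:
                assert not (scaf == p.scaffold and s <= p.end and e >= p.start)
            seen.append((p.scaffold, p.start, p.end))

    def test_mature_locus_helper(self, study):
        for p in study["planted"]:
            scaf, s, e = mature_locus(p)
            slice_ = study["genome"][scaf][s - 1:e]
            if p.strand == "-":
                slice_ = revcomp(slice_)
            assert slice_ == to_dna(p.mature_seq)

    def test_placement_error_when_no_room(self):
        d = small_design()
        d.n_scaffolds, d.scaffold_length, d.n_mirnas = 1, 3700, 60
        g = generate_genome(d)
        with pytest.raises(simulate.PlacementError):
            plant_hairpins(g, d)


def test_expected_category_proportions_sum_to_one():
    d = small_design()
    props = d.expected_category_proportions()
    assert abs(sum(props.values()) - 1.0) < 1e-9
    assert all(0 <= v <= 1 for v in props.values())


def test_invalid_fractions_rejected():
    d = small_design()
    d.mirna_fraction = 0.95  # with contaminants sums past 1
    with pytest.raises(ConfigurationError):
        d.validate()


class TestLibraries:
    def test_degenerate_mixture_all_reads_are_mature(self):
        """contaminants off + one miRNA at 1e6 TPM -> every clean read
        equals the mature sequence."""
        from mirseq.preprocess import clean_reads
        d = SimulationDesign(
            n_mirnas=1, n_scaffolds=1, scaffold_length=5000,
            libraries=[LibrarySpec("L1", "control", "leaf", 2000)],
            mirna_fraction=1.0,
            contaminant_fraction={},
            low_quality_fraction=0.0, short_fraction=0.0,
            no_adapter_fraction=0.0, polya_fraction=0.0, seed=3)
        rng = np.random.default_rng(3)
        g = generate_genome(d, rng)
        g, planted = plant_hairpins(g, d, rng)
        ncrna = {c: [] for c in ("rRNA", "tRNA", "snRNA", "snoRNA")}
        import pandas as pd
        annot = pd.DataFrame(columns=["scaffold", "start", "end", "strand",
                                      "feature", "gene_id"])
        reads, truth = simulate_libraries(planted, d, g, ncrna, annot, rng)
        clean, stats = clean_reads(iter(reads["L1"]), d.adapter3)
        mature = to_dna(planted[0].mature_seq)
        assert len(clean) > 0
        assert set(clean) == {mature}

    def test_byte_identical_fastq_under_fixed_seed(self, tmp_path, study):
        from mirseq.io import write_fastq
        d = study["design"]
        outs = []
        for run in range(2):
            rng = np.random.default_rng(d.seed + 4)
            reads, _ = simulate_libraries(study["planted"], d,
                                          study["genome"], study["ncrna"],
                                          study["annot"], rng)
            p = tmp_path / f"run{run}.fastq"
            write_fastq(reads["LC"], p)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_mirna_clean_read_length_mode_matches_planted(self, study,
                                                          libraries):
        """The length mode of miRNA-derived clean reads equals the modal
        planted mature length."""
        from collections import Counter
        from mirseq.preprocess import trim_adapter
        by_id = {p.id: p for p in study["planted"]}
        lengths = Counter()
        for rid, seq, _q in libraries["reads"]["LC"]:
            if ":mir=" in rid:
                insert = trim_adapter(seq, study["design"].adapter3)
                if insert:
                    lengths[len(insert)] += 1
        truth = libraries["truth"].set_index("mirna_id")
        designed = Counter()
        for mid, p in by_id.items():
            designed[len(p.mature_seq)] += int(truth.loc[mid, "count_LC"])
        assert lengths.most_common(1)[0][0] == designed.most_common(1)[0][0]

    def test_truth_counts_match_emitted_reads(self, libraries):
        truth = libraries["truth"]
        for lib in ("LC", "RS"):
            emitted = {}
            for rid, _s, _q in libraries["reads"][lib]:
                parts = rid.split(":")
                if parts[1].startswith("mir="):
                    mid = parts[1][4:]
                    emitted[mid] = emitted.get(mid, 0) + 1
            for row in truth.itertuples():
                assert emitted.get(row.mirna_id, 0) == getattr(row, f"count_{lib}")


def test_simulate_counts_poisson_means():
    rng = np.random.default_rng(0)
    x, y = simulate.simulate_counts(5000, 1000.0, 1.0, 100_000, rng)
    assert x.mean() == pytest.approx(100, rel=0.05)
    assert y.mean() == pytest.approx(200, rel=0.05)
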