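"""End-to-end pipeline orchestration.

Stages run in a fixed order (simulate -> clean -> map -> categorize ->
known -> novel -> diffexp -> targets -> report); each stage reads the
previous stages' files from the run directory and writes its own before
the next starts, so a run can be resumed from any stage against cached
outputs. A manifest records parameters and SHA-256 hashes of every
output for bit-stability checks.

All coordinates in the run directory are 1-based inclusive.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, diffexpr, known, novel, preprocess, simulate, targets
from .simulate import ADAPTER3_DEFAULT
from .io import (read_fasta, read_json, read_tsv, revcomp, to_rna,
                 write_fasta, write_fastq, write_json, write_tsv)

log = logging.getLogger("mirseq")

STAGES = ["simulate", "clean", "map", "categorize", "known", "novel",
          "diffexp", "targets", "report"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    outdir: str = "mirseq_run"
    seed: int = 42
    # simulate=True builds all inputs; otherwise the paths must exist
    simulate: bool = True
    genome: str | None = None
    libraries: dict = field(default_factory=dict)   # name -> fastq path
    mature_ref: str | None = None
    ncrna_refs: dict = field(default_factory=dict)  # category -> fasta
    gene_annotation: str | None = None
    transcripts: str | None = None
    # stage parameters
    adapter3: str = ADAPTER3_DEFAULT
    min_len: int = 18
    max_len: int = 30
    mean_q: float = 20.0
    max_mismatch: int = 2
    flank_up: int = 200
    flank_down: int = 200
    merge_gap: int = 30
    p_cut: float = 0.01
    lfc_cut: float = 1.0
    contrasts: list = field(default_factory=lambda: [("LC", "LS"), ("RC", "RS")])
    design: dict = field(default_factory=dict)      # SimulationDesign overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        valid = set(cls.__dataclass_fields__)
        unknown = set(raw) - valid
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.contrasts = [tuple(c) for c in cfg.contrasts]
        return cfg

    def validate(self) -> None:
        if not self.simulate:
            missing = [p for p in [self.genome, self.mature_ref,
                                   *self.libraries.values()]
                       if p and not Path(p).exists()]
            if missing:
                raise ConfigError(f"missing input paths: {missing}")
            if self.genome is None or not self.libraries:
                raise ConfigError("genome and libraries are required "
                                  "when simulate is false")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRun:
    def __init__(self, config: PipelineConfig):
        config.validate()
        self.cfg = config
        self.dir = Path(config.outdir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.dir / "manifest.json"
        self.manifest = (read_json(self.manifest_path)
                         if self.manifest_path.exists()
                         else {"stages": {}, "config": asdict(config)})

    # -- helpers ----------------------------------------------------------
    def _record(self, stage: str, outputs: list, t0: float) -> None:
        self.manifest["stages"][stage] = {
            "outputs": {str(p.relative_to(self.dir)): _sha256(p)
                        for p in outputs},
            "seconds": round(time.time() - t0, 3),
        }
        write_json(self.manifest, self.manifest_path)
        log.info("stage %s done (%.1fs)", stage,
                 self.manifest["stages"][stage]["seconds"])

    def path(self, name: str) -> Path:
        return self.dir / name

    def _lib_names(self):
        if self.cfg.simulate:
            dsn = self._design()
            return [l.name for l in dsn.libraries]
        return sorted(self.cfg.libraries)

    def _design(self) -> simulate.SimulationDesign:
        dsn = simulate.SimulationDesign(seed=self.cfg.seed, **self.cfg.design)
        dsn.adapter3 = self.cfg.adapter3
        return dsn

    # -- stages -----------------------------------------------------------
    def stage_simulate(self):
        t0 = time.time()
        dsn = self._design()
        rng = np.random.default_rng(dsn.seed)
        genome = simulate.generate_genome(dsn, rng)
        genome, planted = simulate.plant_hairpins(genome, dsn, rng)
        ncrna = simulate.make_ncrna_refs(dsn, rng)
        annot = simulate.make_gene_annotation(dsn, genome, planted, rng)
        reads, truth = simulate.simulate_libraries(planted, dsn, genome,
                                                   ncrna, annot, rng)
        plan = _default_target_plan(planted)
        transcripts, target_truth = simulate.make_transcriptome(
            planted, plan, seed=dsn.seed + 5)
        outs = []
        p = self.path("genome.fasta"); write_fasta(genome, p); outs.append(p)
        for cat, refs in ncrna.items():
            p = self.path(f"ncrna_{cat}.fasta"); write_fasta(refs, p); outs.append(p)
        p = self.path("gene_annotation.tsv"); write_tsv(annot, p); outs.append(p)
        p = self.path("mature_ref.fasta")
        write_fasta([(pl.id, to_rna(pl.mature_seq)) for pl in planted], p)
        outs.append(p)
        for lib, lst in reads.items():
            p = self.path(f"{lib}.fastq"); write_fastq(lst, p); outs.append(p)
        p = self.path("truth_mirnas.tsv"); write_tsv(truth, p); outs.append(p)
        p = self.path("transcripts.fasta"); write_fasta(transcripts, p); outs.append(p)
        p = self.path("truth_targets.tsv"); write_tsv(target_truth, p); outs.append(p)
        self._record("simulate", outs, t0)

    def stage_clean(self):
        t0 = time.time()
        clean_by_lib, stats = {}, {}
        for lib in self._lib_names():
            fq = (self.path(f"{lib}.fastq") if self.cfg.simulate
                  else Path(self.cfg.libraries[lib]))
            seqs, st = preprocess.clean_reads(
                fq, adapter3=self.cfg.adapter3, min_len=self.cfg.min_len,
                max_len=self.cfg.max_len, mean_q=self.cfg.mean_q)
            clean_by_lib[lib] = seqs
            stats[lib] = st.as_dict()
        tags = preprocess.collapse(clean_by_lib)
        p1 = self.path("unique_tags.tsv")
        write_tsv(tags.reset_index(), p1)
        p2 = self.path("library_stats.json")
        write_json(stats, p2)
        hist_rows = []
        for by in ("unique", "total"):
            hist, mode = preprocess.length_distribution(tags, by=by)
            for length, freq in hist.items():
                hist_rows.append((by, int(length), float(freq), mode))
        p3 = self.path("length_distribution.tsv")
        write_tsv(pd.DataFrame(hist_rows, columns=["by", "length",
                                                   "frequency", "mode"]), p3)
        self._record("clean", [p1, p2, p3], t0)

    def _tags(self) -> pd.DataFrame:
        return read_tsv(self.path("unique_tags.tsv")).set_index("tag")

    def _genome_path(self) -> Path:
        return (self.path("genome.fasta") if self.cfg.simulate
                else Path(self.cfg.genome))

    def stage_map(self):
        t0 = time.time()
        tags = self._tags()
        genome = read_fasta(self._genome_path())
        aligns = annotate.map_tags(tags.index, genome,
                                   max_mismatch=self.cfg.max_mismatch)
        p = self.path("alignments.tsv")
        write_tsv(aligns, p)
        # mapped-read accounting
        stats = read_json(self.path("library_stats.json"))
        mapped = set(aligns.tag)
        for lib in tags.columns:
            m = tags.index.isin(mapped)
            stats[lib]["mapped_unique"] = int((tags[lib][m] > 0).sum())
            stats[lib]["mapped_total"] = int(tags[lib][m].sum())
        p2 = self.path("library_stats.json")
        write_json(stats, p2)
        self._record("map", [p, p2], t0)

    def _references(self):
        if self.cfg.simulate:
            ncrna = {cat: list(read_fasta(self.path(f"ncrna_{cat}.fasta")).items())
                     for cat in ("rRNA", "tRNA", "snRNA", "snoRNA")}
            annot = read_tsv(self.path("gene_annotation.tsv"))
            mature = known.load_mature_fasta(self.path("mature_ref.fasta"))
        else:
            ncrna = {cat: list(read_fasta(p).items())
                     for cat, p in self.cfg.ncrna_refs.items()}
            annot = (read_tsv(self.cfg.gene_annotation)
                     if self.cfg.gene_annotation else
                     pd.DataFrame(columns=["scaffold", "start", "end",
                                           "strand", "feature", "gene_id"]))
            mature = known.load_mature_fasta(self.cfg.mature_ref)
        return ncrna, annot, mature

    def stage_categorize(self):
        t0 = time.time()
        tags = self._tags()
        aligns = read_tsv(self.path("alignments.tsv"))
        ncrna, annot, mature = self._references()
        assign = annotate.categorize(tags.index, aligns, ncrna, annot, mature,
                                     max_mm_mirna=self.cfg.max_mismatch)
        p1 = self.path("categories.tsv"); write_tsv(assign, p1)
        summary = annotate.summarize_categories(assign, tags)
        p2 = self.path("category_summary.tsv"); write_tsv(summary, p2)
        self._record("categorize", [p1, p2], t0)

    def stage_known(self):
        t0 = time.time()
        tags = self._tags()
        assign = read_tsv(self.path("categories.tsv"))
        mirna_tags = assign[assign.category == "miRNA"].tag
        _, _, mature = self._references()
        hits = known.match_table(mirna_tags, mature,
                                 max_mm=self.cfg.max_mismatch)
        per_mature, per_family = known.family_counts(hits, tags)
        det = known.detection_summary(per_mature, libs=list(tags.columns))
        p1 = self.path("known_hits.tsv"); write_tsv(hits, p1)
        p2 = self.path("known_per_mature.tsv"); write_tsv(per_mature, p2)
        p3 = self.path("known_per_family.tsv"); write_tsv(per_family, p3)
        p4 = self.path("known_detection.tsv"); write_tsv(det, p4)
        self._record("known", [p1, p2, p3, p4], t0)

    def stage_novel(self):
        t0 = time.time()
        tags = self._tags()
        assign = read_tsv(self.path("categories.tsv"))
        unann = set(assign[assign.category == "unannotated"].tag)
        aligns = read_tsv(self.path("alignments.tsv"))
        aligns = aligns[aligns.tag.isin(unann)].copy()
        counts = tags.sum(axis=1)
        aligns["count"] = aligns.tag.map(counts).fillna(0).astype(int)
        genome = read_fasta(self._genome_path())
        lens = {k: len(v) for k, v in genome.items()}
        loci = novel.extract_candidate_loci(
            aligns, lens, flank_up=self.cfg.flank_up,
            flank_down=self.cfg.flank_down, merge_gap=self.cfg.merge_gap)
        accepted, n_checked = [], 0
        for w in loci.itertuples():
            n_checked += 1
            seq = genome[w.scaffold][w.start - 1:w.end]
            if w.strand == "-":
                seq = revcomp(seq)
            res = novel.call_precursor(
                seq, w.scaffold, w.start, w.strand,
                [(t, c, s, e) for t, c, s, e in w.tags],
                candidate_id=f"novel-m{n_checked:04d}")
            if isinstance(res, novel.PrecursorCandidate):
                accepted.append(res)
        p1 = self.path("novel_candidates.tsv")
        write_tsv(novel.candidates_table(accepted), p1)
        p2 = self.path("novel.gff3"); novel.write_gff3(accepted, p2)
        bias = novel.first_nt_bias(accepted)
        p3 = self.path("novel_first_nt.json")
        write_json({"windows_checked": n_checked,
                    "accepted": len(accepted),
                    "first_nt": bias}, p3)
        self._record("novel", [p1, p2, p3], t0)

    def stage_diffexp(self):
        t0 = time.time()
        per_mature = read_tsv(self.path("known_per_mature.tsv"))
        stats = read_json(self.path("library_stats.json"))
        totals = {lib: st["clean_reads"] for lib, st in stats.items()}
        counts = per_mature.set_index("mirna_id") if "mirna_id" in per_mature \
            else per_mature.set_index("mature_id")
        outs, summary = [], {}
        for control, treatment in self.cfg.contrasts:
            rec = diffexpr.expression_table(counts, totals, control, treatment)
            rec = diffexpr.call_de(rec, p_cut=self.cfg.p_cut,
                                   lfc_cut=self.cfg.lfc_cut)
            p = self.path(f"diffexp_{control}_vs_{treatment}.tsv")
            write_tsv(rec, p)
            outs.append(p)
            summary[f"{control}_vs_{treatment}"] = diffexpr.de_summary(rec)
        p = self.path("diffexp_summary.json"); write_json(summary, p)
        outs.append(p)
        self._record("diffexp", outs, t0)

    def stage_targets(self):
        t0 = time.time()
        _, _, mature = self._references()
        tr_path = (self.path("transcripts.fasta") if self.cfg.simulate
                   else Path(self.cfg.transcripts))
        if not Path(tr_path).exists():
            write_tsv(pd.DataFrame(columns=["mirna_id", "transcript_id",
                                            "start", "end",
                                            "weighted_mismatches", "states"]),
                      self.path("targets.tsv"))
            self._record("targets", [self.path("targets.tsv")], t0)
            return
        transcripts = read_fasta(tr_path)
        mirnas = {m.id: m.seq for m in mature}
        hits = targets.scan_transcripts(mirnas, transcripts)
        p = self.path("targets.tsv"); write_tsv(hits, p)
        self._record("targets", [p], t0)

    def stage_report(self):
        t0 = time.time()
        lines = ["# mirseq run report", ""]
        stats = read_json(self.path("library_stats.json"))
        lines.append("## Library statistics")
        lines.append("library | raw | high-quality | clean | unique | mapped")
        lines.append("--- | --- | --- | --- | --- | ---")
        for lib, st in sorted(stats.items()):
            lines.append(f"{lib} | {st['raw_reads']} | "
                         f"{st['high_quality_reads']} | {st['clean_reads']} | "
                         f"{st['unique_tags']} | {st.get('mapped_total', 0)}")
        lines.append("")
        for name, title in [("category_summary.tsv", "Category partition"),
                            ("known_per_family.tsv", "Conserved families"),
                            ("novel_candidates.tsv", "Novel candidates"),
                            ("targets.tsv", "Predicted targets")]:
            p = self.path(name)
            if p.exists():
                df = read_tsv(p)
                lines.append(f"## {title} ({len(df)} rows)")
                if len(df):
                    lines.append(df.head(25).round(3).to_string(index=False))
                lines.append("")
        for c, t in self.cfg.contrasts:
            p = self.path(f"diffexp_{c}_vs_{t}.tsv")
            if p.exists():
                df = read_tsv(p)
                sig = df[df.significant]
                lines.append(f"## Differential expression {c} vs {t}: "
                             f"{len(sig)} significant of {len(df)} "
                             f"({(sig.log2fc > 0).sum()} up, "
                             f"{(sig.log2fc < 0).sum()} down)")
                lines.append("")
        p = self.path("report.md")
        p.write_text("\n".join(lines))
        self._record("report", [p], t0)

    def run_all(self, from_stage: str | None = None):
        start = STAGES.index(from_stage) if from_stage else 0
        for name in STAGES[start:]:
            if name == "simulate" and not self.cfg.simulate:
                continue
            getattr(self, f"stage_{name}")()
        return self.manifest


def _default_target_plan(planted):
    """One clean site, one wobble-bearing site and one rejected site,
    cycling through the planted miRNAs."""
    plan = []
    for i, p in enumerate(planted[:6]):
        mature = to_rna(p.mature_seq)
        if i % 3 == 0:
            plan.append((p.id, []))
        elif i % 3 == 1:
            pos = next((k + 1 for k, c in enumerate(mature)
                        if c in "GU" and k + 1 not in (10, 11)), None)
            plan.append((p.id, [(pos, "w")] if pos else []))
        else:
            plan.append((p.id, [(10, "x")]))
    return plan


def run_all(config: PipelineConfig, from_stage: str | None = None):
    """Execute the pipeline; returns the manifest dict."""
    return PipelineRun(config).run_all(from_stage=from_stage)
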