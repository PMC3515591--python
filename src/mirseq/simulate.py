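"""Synthetic small RNA-seq benchmark generator.

Builds, from a single seed, everything the pipeline consumes: a toy
genome with planted miRNA hairpin loci, non-coding RNA reference sets,
a gene annotation table, four adapter-ligated sRNA libraries
(control/stress x leaf/root) with designed per-miRNA abundances and
fold changes, and a toy transcriptome carrying planted target sites.

Every output comes with a truth table so downstream calls (category
assignment, known/novel discovery, differential expression, target
prediction) can be scored without reaching into the generator.

Read counts are Poisson around design means, matching the Poisson
significance model used downstream; optional gamma overdispersion is
off by default. Library sizes default to 1e5 reads: large enough for
stable fold-change recovery at the designed abundances, small enough
to regenerate in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fold as _fold
from .io import revcomp, to_dna, to_rna

ADAPTER3_DEFAULT = "TGGAATTCTCGGGTGCCAAGG"  # Illumina TruSeq small RNA 3'

# fragment length distribution for non-miRNA reads: 24-nt dominant with a
# secondary 21-nt class, the canonical plant sRNA profile
LENGTH_NOISE_DEFAULT = {
    18: 0.02, 19: 0.03, 20: 0.05, 21: 0.15, 22: 0.07, 23: 0.08,
    24: 0.45, 25: 0.06, 26: 0.03, 27: 0.02, 28: 0.02, 29: 0.01, 30: 0.01,
}


class ConfigurationError(ValueError):
    pass


class PlacementError(RuntimeError):
    pass


@dataclass
class LibrarySpec:
    name: str
    condition: str   # 'control' | 'stress'
    tissue: str      # 'leaf' | 'root'
    total_reads: int


@dataclass(frozen=True)
class PlantedMiRNA:
    """A hairpin locus written into the synthetic genome.

    Coordinates are 1-based inclusive on the forward genome strand; for
    strand '-', precursor_seq equals the reverse complement of the
    genome slice. mature/star/precursor sequences are RNA (U alphabet).
    """
    id: str
    mature_seq: str
    star_seq: str
    precursor_seq: str
    scaffold: str
    start: int
    end: int
    strand: str
    arm: str                      # '5p' | '3p'
    design_tpm: dict              # library name -> expected TPM
    design_log2fc: dict           # tissue -> designed stress/control log2 FC


@dataclass
class SimulationDesign:
    n_mirnas: int = 20
    n_scaffolds: int = 2
    scaffold_length: int = 50_000
    libraries: list = field(default_factory=lambda: [
        LibrarySpec("LC", "control", "leaf", 100_000),
        LibrarySpec("LS", "stress", "leaf", 100_000),
        LibrarySpec("RC", "control", "root", 100_000),
        LibrarySpec("RS", "stress", "root", 100_000),
    ])
    mirna_fraction: float = 0.15
    contaminant_fraction: dict = field(default_factory=lambda: {
        "rRNA": 0.10, "tRNA": 0.03, "snRNA": 0.005, "snoRNA": 0.002,
        "exon_sense": 0.04, "exon_antisense": 0.02,
        "intron_sense": 0.04, "intron_antisense": 0.02,
    })
    adapter3: str = ADAPTER3_DEFAULT
    read_length: int = 36
    length_noise: dict = field(default_factory=lambda: dict(LENGTH_NOISE_DEFAULT))
    low_quality_fraction: float = 0.0015
    short_fraction: float = 0.002
    no_adapter_fraction: float = 0.001
    polya_fraction: float = 0.001
    overdispersion: float = 0.0   # gamma CV^2; 0 = pure Poisson
    seed: int = 42

    def validate(self) -> None:
        if self.scaffold_length <= 0 and self.n_scaffolds > 0:
            raise ConfigurationError("scaffold_length must be positive")
        if self.n_scaffolds < 0 or self.n_mirnas < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.n_scaffolds and self.scaffold_length < 10 * 365:
            raise ConfigurationError("scaffolds must be >= 10x the maximum "
                                     "precursor length (3650 nt)")
        fracs = dict(self.contaminant_fraction)
        fracs["miRNA"] = self.mirna_fraction
        for k, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"fraction {k} outside [0,1]")
        if sum(fracs.values()) > 1.0 + 1e-12:
            raise ConfigurationError("category fractions exceed 1")
        for lib in self.libraries:
            if lib.total_reads <= 0:
                raise ConfigurationError("total_reads must be positive")
        if abs(sum(self.length_noise.values()) - 1.0) > 1e-9:
            raise ConfigurationError("length_noise must sum to 1")
        if not self.adapter3 or set(self.adapter3) - set("ACGT"):
            raise ConfigurationError("adapter3 must be a non-empty DNA string")

    def expected_category_proportions(self) -> dict:
        """Expected read-category mix before sampling; sums to 1."""
        out = dict(self.contaminant_fraction)
        out["miRNA"] = self.mirna_fraction
        out["unannotated"] = 1.0 - sum(out.values())
        return out


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


# ---------------------------------------------------------------------------
# genome and hairpins
# ---------------------------------------------------------------------------

def generate_genome(design: SimulationDesign, rng=None) -> dict:
    """Random scaffolds named scaffold_1..n (uniform ACGT)."""
    design.validate()
    rng = rng or np.random.default_rng(design.seed)
    return {f"scaffold_{i + 1}": _random_dna(rng, design.scaffold_length)
            for i in range(design.n_scaffolds)}


def _make_hairpin(rng: np.random.Generator):
    """mature, star, precursor (RNA), arm, mature offset in precursor."""
    L = int(rng.choice([20, 21, 22], p=[0.2, 0.6, 0.2]))
    first = "U" if rng.random() < 0.5 else rng.choice(list("ACG"))
    mature = first + "".join(rng.choice(list("ACGU"), L - 1))
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    star_l = [comp[c] for c in mature[::-1]]
    # up to 2 designed G:U wobbles (star stays reverse-complementary up to
    # <=4 wobble positions per the hairpin contract)
    wobble_sites = [i for i, c in enumerate(mature) if c in "GU"]
    n_wob = int(rng.integers(0, 3))
    for i in rng.permutation(len(wobble_sites))[:n_wob]:
        p = wobble_sites[i]
        star_l[L - 1 - p] = "U" if mature[p] == "G" else "G"
    star = "".join(star_l)
    loop = "".join(rng.choice(list("ACGU"), int(rng.integers(8, 21))))
    tail5 = "".join(rng.choice(list("ACGU"), int(rng.integers(10, 41))))
    tail3 = "".join(rng.choice(list("ACGU"), int(rng.integers(10, 41))))
    arm = "5p" if rng.random() < 0.5 else "3p"
    if arm == "5p":
        pre = tail5 + mature + loop + star + tail3
        off = len(tail5)
    else:
        pre = tail5 + star + loop + mature + tail3
        off = len(tail5) + len(star) + len(loop)
    return mature, star, pre, arm, off


def plant_hairpins(genome: dict, design: SimulationDesign, rng=None):
    """Write n_mirnas hairpin precursors into the genome at random
    non-overlapping loci. Returns (modified genome, list of PlantedMiRNA)."""
    design.validate()
    rng = rng or np.random.default_rng(design.seed + 1)
    if design.n_mirnas == 0:
        return dict(genome), []
    if not genome:
        raise PlacementError("no scaffolds to plant into")
    seqs = {k: list(v) for k, v in genome.items()}
    names = sorted(genome)
    occupied = {k: [] for k in names}
    # designed stress response: a third up, a third down, a third flat
    lfc_cycle = [1.5, -1.5, 0.0]
    planted = []
    for m in range(design.n_mirnas):
        mature, star, pre, arm, off = _make_hairpin(rng)
        pre_dna = to_dna(pre)
        placed = False
        for _ in range(200):
            scaf = names[int(rng.integers(0, len(names)))]
            start0 = int(rng.integers(0, len(seqs[scaf]) - len(pre_dna)))
            end0 = start0 + len(pre_dna) - 1
            if any(s - 50 <= end0 and e + 50 >= start0 for s, e in occupied[scaf]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            insert = pre_dna if strand == "+" else revcomp(pre_dna)
            seqs[scaf][start0:end0 + 1] = list(insert)
            occupied[scaf].append((start0, end0))
            base_tpm = float(10 ** rng.uniform(1.5, 4.0))
            lfc = {"leaf": lfc_cycle[m % 3], "root": lfc_cycle[(m + 1) % 3]}
            tpm = {}
            for lib in design.libraries:
                scale = 2.0 ** lfc[lib.tissue] if lib.condition == "stress" else 1.0
                tpm[lib.name] = base_tpm * scale
            planted.append(PlantedMiRNA(
                id=f"syn-mir-{m + 1:04d}", mature_seq=mature, star_seq=star,
                precursor_seq=pre, scaffold=scaf, start=start0 + 1,
                end=end0 + 1, strand=strand, arm=arm,
                design_tpm=tpm, design_log2fc=lfc))
            placed = True
            break
        if not placed:
            raise PlacementError(f"no room for hairpin {m + 1}")
    genome2 = {k: "".join(v) for k, v in seqs.items()}
    # normalize TPMs so the control-library miRNA mass matches the design
    total = sum(p.design_tpm[design.libraries[0].name] for p in planted)
    factor = design.mirna_fraction * 1e6 / total if total else 0.0
    planted = [PlantedMiRNA(
        id=p.id, mature_seq=p.mature_seq, star_seq=p.star_seq,
        precursor_seq=p.precursor_seq, scaffold=p.scaffold, start=p.start,
        end=p.end, strand=p.strand, arm=p.arm,
        design_tpm={k: v * factor for k, v in p.design_tpm.items()},
        design_log2fc=p.design_log2fc) for p in planted]
    return genome2, planted


# ---------------------------------------------------------------------------
# reference sets and annotation
# ---------------------------------------------------------------------------

_NCRNA_SIZES = {"rRNA": [1600, 900], "tRNA": [76, 74, 75, 73, 77],
                "snRNA": [160, 145, 190], "snoRNA": [110, 130, 95]}


def make_ncrna_refs(design: SimulationDesign, rng=None) -> dict:
    """Synthetic stand-ins for rRNA/tRNA/snRNA/snoRNA reference sets
    (random sequences; only their fragments matter downstream)."""
    rng = rng or np.random.default_rng(design.seed + 2)
    return {cat: [(f"{cat}_{i + 1}", _random_dna(rng, n))
                  for i, n in enumerate(sizes)]
            for cat, sizes in _NCRNA_SIZES.items()}


def make_gene_annotation(design: SimulationDesign, genome: dict,
                         planted, rng=None) -> pd.DataFrame:
    """Exon/intron intervals (1-based inclusive) avoiding planted loci.

    Columns: scaffold, start, end, strand, feature, gene_id.
    """
    rng = rng or np.random.default_rng(design.seed + 3)
    blocked = {}
    for p in planted:
        blocked.setdefault(p.scaffold, []).append((p.start - 100, p.end + 100))
    rows = []
    gid = 0
    for scaf in sorted(genome):
        glen = len(genome[scaf])
        for _ in range(max(2, glen // 15_000)):
            for _try in range(50):
                span = int(rng.integers(1200, 3000))
                start = int(rng.integers(1, max(2, glen - span)))
                end = start + span - 1
                if any(s <= end and e >= start for s, e in blocked.get(scaf, [])):
                    continue
                gid += 1
                strand = "+" if rng.random() < 0.5 else "-"
                n_ex = int(rng.integers(2, 5))
                cuts = np.sort(rng.choice(np.arange(start + 100, end - 100, 50),
                                          size=2 * (n_ex - 1), replace=False))
                bounds = [start, *cuts.tolist(), end]
                for k in range(0, len(bounds) - 1, 2):
                    rows.append((scaf, bounds[k], bounds[k + 1], strand,
                                 "exon", f"gene_{gid:03d}"))
                    if k + 2 < len(bounds):
                        rows.append((scaf, bounds[k + 1] + 1, bounds[k + 2] - 1,
                                     strand, "intron", f"gene_{gid:03d}"))
                blocked.setdefault(scaf, []).append((start, end))
                break
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "strand",
                                       "feature", "gene_id"])


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

def _sample_length(rng, dist):
    ls = sorted(dist)
    return int(rng.choice(ls, p=[dist[l] for l in ls]))


def _quality(rng, n, low=False):
    if low:
        return list(rng.integers(2, 10, n))
    return list(rng.integers(32, 41, n))


def _ligate(insert: str, design: SimulationDesign, rng, with_adapter=True):
    if with_adapter:
        read = insert + design.adapter3
    else:
        read = insert + _random_dna(rng, design.read_length)
    read = (read + "A" * design.read_length)[:design.read_length]
    return read


def _interval_fragment(rng, genome, scaf, start, end, length, antisense):
    if end - start + 1 < length:
        return None
    s0 = int(rng.integers(start - 1, end - length + 1))
    frag = genome[scaf][s0:s0 + length]
    return revcomp(frag) if antisense else frag


def simulate_libraries(planted, design: SimulationDesign, genome: dict,
                       ncrna_refs: dict, gene_annot: pd.DataFrame, rng=None):
    """Simulate the four libraries.

    Returns (reads, truth): reads maps library name to a list of
    (read id, sequence, qualities); read ids encode the true source
    category ('<lib>:<truth>:<serial>'). truth is a per-miRNA table of
    designed TPM and sampled read counts per library.
    """
    design.validate()
    rng = rng or np.random.default_rng(design.seed + 4)
    exons = gene_annot[gene_annot.feature == "exon"]
    introns = gene_annot[gene_annot.feature == "intron"]
    gene_like = {"exon_sense": (exons, False), "exon_antisense": (exons, True),
                 "intron_sense": (introns, False),
                 "intron_antisense": (introns, True)}
    blocked = []
    for p in planted:
        blocked.append((p.scaffold, p.start, p.end))
    for _, r in gene_annot.iterrows():
        blocked.append((r.scaffold, r.start, r.end))

    reads = {}
    truth_rows = []
    counts_by_lib = {}
    for lib in design.libraries:
        lam = np.array([p.design_tpm[lib.name] * lib.total_reads / 1e6
                        for p in planted])
        if design.overdispersion > 0 and len(lam):
            shape = 1.0 / design.overdispersion
            lam = rng.gamma(shape, lam / shape)
        counts_by_lib[lib.name] = rng.poisson(lam) if len(lam) else np.array([], int)

    for p_i, p in enumerate(planted):
        row = {"mirna_id": p.id, "mature_seq": p.mature_seq,
               "scaffold": p.scaffold, "start": p.start, "end": p.end,
               "strand": p.strand, "arm": p.arm,
               "log2fc_leaf": p.design_log2fc["leaf"],
               "log2fc_root": p.design_log2fc["root"]}
        for lib in design.libraries:
            row[f"tpm_{lib.name}"] = p.design_tpm[lib.name]
            row[f"count_{lib.name}"] = int(counts_by_lib[lib.name][p_i])
        truth_rows.append(row)

    for lib in design.libraries:
        out = []
        serial = 0

        def emit(insert, tag, with_adapter=True, low=False, polya=False):
            nonlocal serial
            serial += 1
            if polya:
                insert = insert + "A" * 6
            read = _ligate(to_dna(insert), design, rng, with_adapter)
            out.append((f"{lib.name}:{tag}:{serial:07d}", read,
                        _quality(rng, len(read), low)))

        # planted miRNA reads
        for p_i, p in enumerate(planted):
            for _ in range(int(counts_by_lib[lib.name][p_i])):
                emit(p.mature_seq, f"mir={p.id}")
        # ncRNA contaminants
        for cat in ("rRNA", "tRNA", "snRNA", "snoRNA"):
            n = rng.poisson(design.contaminant_fraction.get(cat, 0.0)
                            * lib.total_reads)
            refs = ncrna_refs[cat]
            for _ in range(n):
                rid, rseq = refs[int(rng.integers(0, len(refs)))]
                length = min(_sample_length(rng, design.length_noise), len(rseq))
                s0 = int(rng.integers(0, len(rseq) - length + 1))
                emit(rseq[s0:s0 + length], cat)
        # gene-derived fragments
        for cat, (feats, anti) in gene_like.items():
            n = rng.poisson(design.contaminant_fraction.get(cat, 0.0)
                            * lib.total_reads)
            if not len(feats):
                n = 0
            for _ in range(n):
                r = feats.iloc[int(rng.integers(0, len(feats)))]
                frag = _interval_fragment(
                    rng, genome, r.scaffold, r.start, r.end,
                    _sample_length(rng, design.length_noise), anti)
                if frag:
                    emit(frag, cat)
        # unannotated genome fragments
        resid = design.expected_category_proportions()["unannotated"]
        n = rng.poisson(resid * lib.total_reads)
        scafs = sorted(genome)
        for _ in range(n):
            for _try in range(20):
                scaf = scafs[int(rng.integers(0, len(scafs)))]
                length = _sample_length(rng, design.length_noise)
                s0 = int(rng.integers(0, len(genome[scaf]) - length))
                lo, hi = s0 + 1, s0 + length
                if any(sc == scaf and s <= hi and e >= lo
                       for sc, s, e in blocked):
                    continue
                frag = genome[scaf][s0:s0 + length]
                emit(frag if rng.random() < 0.5 else revcomp(frag), "unann")
                break
        # cleaning-stage exercise reads
        for _ in range(rng.poisson(design.low_quality_fraction * lib.total_reads)):
            emit(_random_dna(rng, 24), "lowq", low=True)
        for _ in range(rng.poisson(design.short_fraction * lib.total_reads)):
            emit(_random_dna(rng, int(rng.integers(8, 18))), "short")
        for _ in range(rng.poisson(design.no_adapter_fraction * lib.total_reads)):
            emit(_random_dna(rng, 25), "noadapt", with_adapter=False)
        for _ in range(rng.poisson(design.polya_fraction * lib.total_reads)):
            emit(_random_dna(rng, 20), "polya", polya=True)
        order = rng.permutation(len(out))
        reads[lib.name] = [out[i] for i in order]
    return reads, pd.DataFrame(truth_rows)


def simulate_counts(n: int, tpm, log2fc, total_reads: int, rng):
    """Count-level shortcut used for calibration studies: Poisson counts
    for a control library and a stress library at the given TPMs and
    designed per-miRNA log2 fold changes. Returns (x, y) arrays."""
    tpm = np.broadcast_to(np.asarray(tpm, float), (n,))
    lfc = np.broadcast_to(np.asarray(log2fc, float), (n,))
    lam_c = tpm * total_reads / 1e6
    lam_t = lam_c * 2.0 ** lfc
    return rng.poisson(lam_c), rng.poisson(lam_t)


# ---------------------------------------------------------------------------
# transcriptome with planted target sites
# ---------------------------------------------------------------------------

_COMP_RNA = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE_TARGET = {"G": "U", "U": "G"}


def make_transcriptome(planted, mismatch_plan, seed: int,
                       transcript_length: int = 1000, n_decoys: int = 5):
    """Transcripts with planted miRNA target sites.

    mismatch_plan: list of (mirna_id, [(position, kind), ...]) with
    1-based positions from the miRNA 5' end and kind 'x' (mismatch) or
    'w' (G:U wobble; only valid where the miRNA base is G or U).

    Returns (transcripts dict id->DNA seq, truth DataFrame with the
    planted site coordinates and the planned per-position states).
    """
    rng = np.random.default_rng(seed)
    by_id = {p.id: p for p in planted}
    transcripts = {}
    rows = []
    for t_i, (mid, plan) in enumerate(mismatch_plan):
        mature = to_rna(by_id[mid].mature_seq)
        L = len(mature)
        states = ["m"] * L
        # perfect site = reverse complement of the mature, 5'->3'
        site = [_COMP_RNA[c] for c in mature[::-1]]
        for pos, kind in plan:
            if not 1 <= pos <= L:
                raise ConfigurationError(f"plan position {pos} outside 1..{L}")
            w_i = L - pos  # site index pairing miRNA position pos
            if kind == "w":
                if mature[pos - 1] not in _WOBBLE_TARGET:
                    raise ConfigurationError(
                        f"no wobble possible at position {pos} "
                        f"(miRNA base {mature[pos - 1]})")
                site[w_i] = _WOBBLE_TARGET[mature[pos - 1]]
            elif kind == "x":
                banned = {_COMP_RNA[mature[pos - 1]],
                          _WOBBLE_TARGET.get(mature[pos - 1], "")}
                choices = [b for b in "ACGU" if b not in banned]
                site[w_i] = choices[int(rng.integers(0, len(choices)))]
            else:
                raise ConfigurationError(f"unknown plan kind {kind!r}")
            states[pos - 1] = kind
        tid = f"transcript_{t_i + 1:03d}"
        body = _random_dna(rng, transcript_length)
        s0 = int(rng.integers(50, transcript_length - L - 50))
        seq = body[:s0] + to_dna("".join(site)) + body[s0 + L:]
        transcripts[tid] = seq
        rows.append({"mirna_id": mid, "transcript_id": tid,
                     "site_start": s0 + 1, "site_end": s0 + L,
                     "states": "".join(states)})
    for d in range(n_decoys):
        transcripts[f"decoy_{d + 1:03d}"] = _random_dna(rng, transcript_length)
    return transcripts, pd.DataFrame(
        rows, columns=["mirna_id", "transcript_id", "site_start",
                       "site_end", "states"])


def mature_locus(p: PlantedMiRNA):
    """Forward-strand 1-based inclusive genome coordinates of the planted
    mature within its precursor locus."""
    off = to_dna(p.precursor_seq).find(to_dna(p.mature_seq))
    L = len(p.mature_seq)
    if p.strand == "+":
        start = p.start + off
        return p.scaffold, start, start + L - 1
    end = p.end - off
    return p.scaffold, end - L + 1, end


def planted_mature_fasta(planted) -> list:
    """(id, RNA seq) records for the planted matures, usable as a
    known-miRNA reference ('id family species' headers)."""
    return [(p.id, to_rna(p.mature_seq)) for p in planted]
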