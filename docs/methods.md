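# Methods

This note records the models, parameter choices and numerical
conventions behind each stage, the assumptions they rest on, and what
the synthetic benchmark does and does not demonstrate.

## Read cleaning

Raw reads pass four gates in a fixed order: (1) quality — mean Phred
>= 20 and at most one N per read; (2) 3' adapter — the leftmost read
position whose suffix matches a prefix of the adapter with >= 6 nt
overlap and at most 1 mismatch per 10 nt of overlap; reads with no
detectable adapter are discarded, because in a size-selected small-RNA
library an invisible adapter means the insert ran past the read end;
(3) trailing poly-A runs of >= 6 nt are stripped; (4) the insert must
be 18–30 nt. The quality and poly-A thresholds are explicit,
configurable stand-ins for cleaning rules that sRNA-seq pipelines
rarely publish precisely; the synthetic generator injects reads that
each gate must remove, so generator and cleaner agree by construction.
Conservation is enforced as an invariant: raw = clean + sum of removed,
per reason.

All sequences are normalized to the DNA alphabet (T) internally; RNA
input (U) is accepted everywhere and mature/precursor sequences are
reported back as RNA.

## Genome mapping and categorization

Mapping is ungapped with <= 2 substitutions on both strands
(configurable), reported with 1-based inclusive forward-strand
coordinates. The implementation is a pigeonhole seed index — any
alignment with <= k mismatches contains an exact match among k+1 tag
chunks — with base-by-base verification; the test suite checks it
against a brute-force sliding-window scan.

Each tag receives exactly one category with the fixed priority
rRNA > tRNA > snRNA > snoRNA > miRNA > exon-sense > exon-antisense >
intron-sense > intron-antisense > unannotated. ncRNA membership is
exact substring containment in the reference set (either orientation);
known-miRNA membership allows <= 2 mismatches; gene overlap uses the
best (fewest-mismatch) alignments, ties broken by the priority order
and then the leftmost coordinate. "Unannotated" is the residual class,
which is what makes the partition sums exact (unique counts sum to the
library's unique tags, totals to its clean reads). Sense/antisense is
defined relative to the annotated gene strand. The category of a tag
is a property of its sequence, not of the library it came from.

## Known-miRNA identification

Tags are compared against a mature reference at every end offset
within +-2 nt (isomiR-style 5'/3' shifts), counting mismatched
overlapping bases plus any tag overhang beyond the mature; hits need
<= 2 total. Each tag is credited once, to its best mature (fewest
mismatches, then smallest |offset|, then lexicographic id), keeping
the count tables consistent with the category partition. The
production path is a vectorized comparison over length-grouped tag
matrices; the scalar routine, which the tests also compare against a
brute-force oracle, defines the semantics. A flag restricts counting
to exact matches for sensitivity analyses; the default includes
<= 2-mismatch hits. Detection tallies report matures with >= 1 read
and with more than 50 reads (strict >) per library.

## RNA folding

`fold()` is a Zuker-style free-energy minimization over a
nearest-neighbor model: a 6x6 dinucleotide stacking table
(Watson–Crick block from the Xia/Turner set, wobble-involving stacks
approximate), size-dependent hairpin/bulge/internal-loop penalties
with Jacobson–Stockmayer log extrapolation above tabulated sizes, and
an affine multiloop term (a = 3.4, b = 0.4 per branch, c = 0.1 per
unpaired base, kcal/mol). Hairpin loops need >= 3 unpaired bases;
bulge/internal loops are capped at 30 unpaired bases in the search;
G:U wobbles pair. The model deliberately omits dangling ends,
terminal-AU penalties, special tetraloops and loop-sequence terms:
the pipeline needs stable stem/arm classification, not chemically
exact energies, and the omissions keep the model exactly re-scorable.

Energies are integer centi-kcal/mol throughout, so three independent
paths agree exactly: the DP minimum, a loop-decomposition re-scoring
of any structure, and an exhaustive enumeration of all nested
structures (the test oracle for sequences <= 14 nt). Traceback is
deterministic (fixed case order), and the suite asserts that the
traced structure re-scores to the DP minimum, which pins down ties
without prescribing which co-optimal structure wins. Sequences with
no canonical pair fold to the open chain at exactly 0.

## Novel precursor calling

Nearby mapped unannotated tags (gap <= 30 nt) are clustered; windows
are cluster extents +- 200 nt flanks clipped to the scaffold, strand
by read-count majority. Inside a window the putative mature is the
most abundant 18–26 nt tag (ties: longer, then 5'-most), taken as the
genomic sequence under the tag so mismatched alignments still anchor
a locus. Windows longer than the 400-nt folding cap are trimmed
symmetrically around the mature before folding.

Acceptance requires, in reporting order: one linear helix chain
through the mature/star region (opening positions ascending implies
partners strictly descending — bulges and internal loops allowed,
branching not); the mature entirely on one arm; >= 16 mature bases
paired; <= 4 unpaired mature bases and <= 2 nt mature/star length
asymmetry; precursor MFE <= −18 kcal/mol; precursor length 70–365 nt.
The precursor slice is the stem span, grown outward through enclosing
pairs while the stem stays linear, then padded symmetrically to the
70-nt floor. Because planted precursors carry 10–40 nt of
unstructured random tail, the called locus is validated as covering
the mature/star duplex and overlapping the planted locus rather than
as coordinate-identical to it. Rejections carry the first failed
criterion. G:U counts as paired everywhere in these rules.

## Differential expression

TPM = count / clean-read total x 10^6. Fold change =
log2(max(TPM_t, 0.01) / max(TPM_c, 0.01)); the 0.01 floor keeps
zero-count contrasts finite and direction-preserving and is
configurable. Significance uses the Audic–Claverie conditional
measure in the symmetric exponent-(x+y) form

    q(y|x) = t^y (x+y)! / ( x! y! (1+t)^(x+y) ),   t = N2/N1,

which satisfies q(y|x; N1,N2) = q(x|y; N2,N1) pointwise. The measure
totals (1+t); tails are accumulated via the negative-binomial
identity q(k|x) = (1+t) NB(k; x+1, 1/(1+t)) using scipy's
regularized-beta CDF/SF in log space (no explicit factorials; counts
in the millions are exact to ~1e-14 against direct log-space
summation). The two-sided p is 2 min(lower, upper) capped at 1; the
doubled-tail form is exactly symmetric at x = y with equal depths and
near-symmetric otherwise. Calls require p < 0.01 and |log2FC| > 1.
Raw p-values are the default — the upstream design pools biological
replicates before sequencing, so there is no dispersion to estimate —
with optional Benjamini–Hochberg adjustment behind a flag.

Under the synthetic null (designed fold change 0, the generator's
log-uniform abundance distribution, 1e5 reads per library) the
pooled type-I fraction at p < 0.01 is ~0.004-0.005 — conservative, as
expected from a discrete test doubled and capped — and power at a
designed log2FC of 1.5 and TPM >= 1000 is ~1. Designed fold changes
at high abundance are recovered within ±0.2 log2 units, the scale of
Poisson counting noise at these depths.

## Target prediction

The duplex model is ungapped: the five positional criteria are
undefined under bulged alignments, and word-match scans (the field's
standard here) do not gap. Positions are 1-based from the miRNA 5'
end; "positions 1–12" includes position 1. A wobble contributes 0.5
to the weighted totals (criteria i and v) but does not count as a
"mismatch" for the adjacency/positional rules (ii–iv) by default —
Allen-style scoring — with a strict mode that treats wobbles as
mismatches everywhere. Criterion ii is read as "no run of more than
two adjacent mismatches"; criterion iii as "no two adjacent
mismatches both within positions 2–12". Every transcript window is
scanned in the antisense orientation on the given strand only. The
rule engine is a pure function of the per-position state vector and
is tested for exact agreement with a clause-by-clause re-evaluation
on random mismatch/wobble masks.

## Synthetic-data generator

The generator emulates the four-library stress design: scaffolds of
uniform random sequence; planted hairpins built as 10–40 nt tail +
mature (20–22 nt, first nucleotide U with probability 0.5) + 8–20 nt
loop + near-reverse-complement star (0–2 designed G:U wobbles) +
tail, placed non-overlapping on either strand; per-miRNA abundances
log-uniform over 10^1.5–10^4 TPM rescaled so the control-library
miRNA mass matches the designed category fraction; stress libraries
shift one third of miRNAs up 1.5 log2 units, one third down, one
third not at all, per tissue. Read counts are Poisson around
TPM x depth / 10^6 (optional gamma overdispersion, off by default,
matching the downstream Poisson test). Reads are 36 nt,
adapter-ligated, Phred+33 with mean Q ~ 36; designed fractions of
low-quality (mean Q < 10), short (< 18 nt), adapter-less and
poly-A-tailed reads exercise each cleaning gate. Contaminants are
fragments of synthetic rRNA/tRNA/snRNA/snoRNA references and of
exon/intron intervals, plus unannotated genome fragments, drawn with
a 24-nt-dominant length distribution (secondary 21-nt class) — the
canonical plant sRNA profile. Read identifiers encode the true source
category, and truth tables carry designed TPMs, sampled counts, loci
and target-site plans, so every downstream call is scoreable without
reading the generator's internals. Default library size is 1e5 reads:
large enough for stable fold-change recovery at the designed
abundances, small enough to regenerate in seconds.

What the generator does **not** emulate: sequencing substitution
errors beyond none (inserts are exact), isomiR end heterogeneity,
expression-correlated GC bias, genomic repeats, spliced transcripts,
and real ncRNA sequence composition (references are random and are
labelled synthetic). Passing the benchmark therefore demonstrates the
correctness of the machinery — accounting, partitions, statistics,
structure criteria, rule logic — on data matching the model's
assumptions, not robustness to artifacts real libraries may carry.

## Problem sizes and determinism

The test suite and the acceptance script run the study at reduced
scale as the package's own validation design: 4 x 2e4–1e5 reads,
8–50 planted miRNAs on 2–5 scaffolds of 40 kb, 100 random windows for
the hairpin false-accept rate, 1000 miRNAs x 20 seeds for null
calibration, 200 sequences for the folding oracle and 3000 masks for
the rule engine. Every random draw flows from one integer seed
through `numpy.random.default_rng` / `random.Random`; fixed seeds
give byte-identical FASTA/FASTQ and bit-stable stage outputs, which
the pipeline manifest (SHA-256 per output) makes checkable.

## Known limitations

No spliced or gapped alignment; no repeat annotation; no
randfold-style shuffling p-values, cross-species conservation
filtering or star-read ratio tests for novel candidates; no
replicate-based dispersion estimation; target prediction has no
expectation/UPE scoring and no degradome support. GO/KEGG annotation
of targets is out of scope (external database services). Locus-level
reporting is used for novel candidates: identical hairpin sequences
at different loci are distinct candidates.
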