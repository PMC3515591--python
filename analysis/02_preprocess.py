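"""Clean the four raw libraries (quality, adapter, poly-A, 18-30 nt),
collapse to unique tags and report the read-accounting ledger and the
length distribution."""

from runconfig import config

from mirseq.io import read_json, read_tsv
from mirseq.pipeline import PipelineRun

run = PipelineRun(config())
run.stage_clean()

stats = read_json(run.path("library_stats.json"))
print("library  raw      high-quality  clean    unique")
for lib, st in sorted(stats.items()):
    print(f"{lib:7s}  {st['raw_reads']:<8d} {st['high_quality_reads']:<13d} "
          f"{st['clean_reads']:<8d} {st['unique_tags']}")
    print(f"         removed: {st['removed']}")

hist = read_tsv(run.path("length_distribution.tsv"))
total = hist[hist.by == "total"].set_index("length")
print("\nread-length distribution (by total reads):")
for length, row in total.iterrows():
    bar = "#" * int(row.frequency * 120)
    print(f"  {length:2d} nt {row.frequency:6.3f} {bar}")
print(f"modal length: {int(total['mode'].iloc[0])} nt")
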