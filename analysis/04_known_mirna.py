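"""Identify known mature miRNAs (<=2 mismatches, +-2 nt end shifts
against the mature reference) and tally detection per library."""

from runconfig import config

from mirseq.io import read_tsv
from mirseq.pipeline import PipelineRun

run = PipelineRun(config())
run.stage_known()

det = read_tsv(run.path("known_detection.tsv"))
print("per-library known-miRNA detection (>=1 read / >50 reads):")
for row in det.itertuples():
    print(f"  {row.library}: {row.detected} detected, "
          f"{row.above_cut} with more than 50 reads")

per_mature = read_tsv(run.path("known_per_mature.tsv"))
top = per_mature.sort_values("LC", ascending=False).head(5)
print("\nmost abundant matures in LC:")
for r in top.itertuples():
    print(f"  {r.mature_id}: LC={r.LC} LS={r.LS} RC={r.RC} RS={r.RS}")
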