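"""Scan the transcriptome for miRNA target sites under the five
complementarity rules and score the hits against the planted plan."""

from runconfig import config

from mirseq.io import read_tsv
from mirseq.pipeline import PipelineRun
from mirseq.reference import target_rules_direct

run = PipelineRun(config())
run.stage_targets()

hits = read_tsv(run.path("targets.tsv"))
truth = read_tsv(run.path("truth_targets.tsv"))
print(f"accepted target sites: {len(hits)}")

recovered = 0
expected = 0
for row in truth.itertuples():
    should = target_rules_direct(row.states)
    expected += should
    hit = hits[(hits.mirna_id == row.mirna_id)
               & (hits.transcript_id == row.transcript_id)
               & (hits.start == row.site_start)]
    recovered += should and len(hit) == 1
print(f"planted accept-able sites recovered: {recovered}/{expected}")
extras = len(hits) - recovered
print(f"hits beyond planted sites: {extras}")
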