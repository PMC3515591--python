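"""Render the final run report aggregating every stage's tables."""

from runconfig import config

from mirseq.pipeline import PipelineRun

run = PipelineRun(config())
run.stage_report()
print(f"report written to {run.path('report.md')}")
print(run.path("report.md").read_text()[:1500])
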