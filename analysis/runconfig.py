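"""Shared configuration for the numbered analysis drivers.

One synthetic study at the generator's default design: four libraries
(leaf/root x control/drought) of 100k reads each, 20 planted miRNA
hairpins with designed stress responses, ncRNA contaminants and a
24-nt-dominant background. All drivers operate on the same run
directory so each stage builds on the previous one.
"""

from pathlib import Path

from mirseq.pipeline import PipelineConfig

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "run"
SEED = 42


def config() -> PipelineConfig:
    return PipelineConfig(outdir=str(RUN_DIR), seed=SEED)
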