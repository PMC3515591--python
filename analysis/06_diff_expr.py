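"""TPM-normalize per-miRNA counts, compute log2 fold changes and
Audic-Claverie p-values for the leaf and root contrasts, and compare
the calls with the designed truth."""

from runconfig import config

from mirseq.io import read_json, read_tsv
from mirseq.pipeline import PipelineRun

run = PipelineRun(config())
run.stage_diffexp()

summary = read_json(run.path("diffexp_summary.json"))
for contrast, s in summary.items():
    print(f"{contrast}: {s['significant']} of {s['n']} significant "
          f"({s['up']} up, {s['down']} down)")

truth = read_tsv(run.path("truth_mirnas.tsv")).set_index("mirna_id")
rec = read_tsv(run.path("diffexp_LC_vs_LS.tsv")).set_index("mirna_id")
joined = rec.join(truth[["log2fc_leaf"]])
err = (joined.log2fc - joined.log2fc_leaf).abs()
high = joined[joined.tpm_control >= 1000]
print(f"\nleaf contrast, designed vs estimated log2FC:")
print(f"  mean |error| (all): {err.mean():.3f}")
print(f"  mean |error| (TPM >= 1000): "
      f"{(high.log2fc - high.log2fc_leaf).abs().mean():.3f}")
flat = joined[joined.log2fc_leaf == 0]
print(f"  false calls among designed-flat miRNAs: "
      f"{int(flat.significant.sum())} of {len(flat)}")
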