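"""Analyse the simulated RNAi screen and compare calls with ground truth.

Primary tier: thrashing-assay classification (>=10% relative survival
change on >=3 of 4 scoring days, no opposing day).  Confirmation tier:
log-rank test of each preliminary hit's lifespan curve against control at
alpha = 0.05 with a direction check.  The script then scores the verified
calls against the planted effect genes recorded in truth.json.
"""

import json
from pathlib import Path

from longnet.pipeline import PipelineConfig, run_screen_stats

WORLD = Path("results/world")
OUT = Path("results/predict")   # shares candidates.tsv written by step 04

config = PipelineConfig(
    survival=str(WORLD / "survival.csv"),
    thrashing=str(WORLD / "thrashing.csv"),
    out_dir=str(OUT),
    baseline_freqs=(0.54, 0.22),   # genome-wide long-lived screen baselines
)
report = run_screen_stats(config)

total = report["funnel"]["total"]
print(f"screened: {total['genes_screened']}; preliminary "
      f"{total['preliminary_long']} long / {total['preliminary_short']} short; "
      f"verified {total['verified_long']} long / {total['verified_short']} short")
print(f"verification frequency: {report['verification_frequency']['long_pct']}% "
      f"long, {report['verification_frequency']['short_pct']}% short")
if "fold_improvement" in report:
    print(f"fold improvement vs genome-wide baselines: "
          f"{report['fold_improvement']['rounded']}x")

truth = json.loads((WORLD / "truth.json").read_text())
planted = set(truth["effect_genes_long"]) | set(truth["effect_genes_short"])
effects = [line.split("\t")[0]
           for line in (OUT / "effects.tsv").read_text().splitlines()[1:]]
recovered = planted & set(effects)
print(f"planted effect genes recovered among verified calls: "
      f"{len(recovered)}/{len(planted)} ({100 * len(recovered) / len(planted):.0f}%)")
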