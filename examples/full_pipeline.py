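"""Run the whole analysis from a single YAML config.

One config drives dataset construction (here synthetic; point the [data]
section at CSVs for a real record), the four-model fits, Bayes factors,
convergence diagnostics and figures.  Everything lands in an output
directory with a manifest tying artifacts to the config and seeds.
"""

import json
from pathlib import Path

import yaml

from countflux.pipeline import run_pipeline

config = {
    "synthetic": {"n_years": 200, "seed": 7},
    "mcmc": {"n_iterations": 20_000, "burn_in": 1_000, "seed": 1},
    "compare": {"widen_factor": 10.0},  # rerun with 10x wider priors
}
Path("pipeline_config.yml").write_text(yaml.safe_dump(config))

out = run_pipeline("pipeline_config.yml", "pipeline_run")

print(f"artifacts in {out}/:")
for p in sorted(out.rglob("*")):
    if p.is_file():
        print(" ", p.relative_to(out))

manifest = json.loads((out / "manifest.json").read_text())
print()
print("Bayes-factor ratios under 10x wider priors (prior sensitivity):")
for model, ratio in manifest["artifacts"].get("bf_ratios", {}).items():
    print(f"  {model}: {ratio:.2f}")
print("wider priors shrink Bayes factors mechanically; the direction of")
print("evidence, not the exact value, is the robust quantity.")
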