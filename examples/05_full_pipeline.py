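"""Run the whole pipeline from a YAML config.

Generates the landscape, ranks it, writes performance curves, runs the
reciprocal surrogacy analysis, evaluates a protected-area mask and
produces the mask-constrained expansion ranking — every artifact hashed
into a run manifest, byte-reproducible under the same seed.
"""

import json
from pathlib import Path

import yaml

from conplan import RunConfig, run_pipeline

config = {
    "seed": 8,
    "n_random_runs": 10,
    "outdir": "scratch/pipeline_run",
}
path = Path("scratch/pipeline_config.yaml")
path.parent.mkdir(exist_ok=True)
path.write_text(yaml.safe_dump(config))

manifest = run_pipeline(RunConfig.from_yaml(path))
print("stages:", " -> ".join(manifest["stages"]))
print("artifacts:")
for name, sha in manifest["artifacts"].items():
    print(f"  {name:22s} {sha[:12]}")

surr = json.loads((Path(config["outdir"]) / "surrogacy.json").read_text())
for key, r in surr.items():
    print(f"{key}: SAI = {r['sai']:.3f}")
# Re-running this script reproduces identical hashes: the whole analysis
# is a pure function of the config and its seed.
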