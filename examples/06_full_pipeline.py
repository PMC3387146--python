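"""Run every stage end to end from one config and inspect the run directory.

Counts-mode run: simulate cohort -> normalize -> association -> CV, with a
manifest digesting every output for provenance.
"""

import json
from pathlib import Path

from ampliclass.pipeline import run_pipeline, validate_config

config = {
    "seed": 0,
    "simulate": {"mode": "counts",
                 "n_per_class": {"control": 60, "IBD": 60},
                 "n_taxa": 200,
                 "planted": {"n_effects": 10, "lfc": 1.5}},
    "assoc": {"label": "label", "q_threshold": 0.05},
    "cv": {"k": 10, "repeats": 3, "n_trees": 500, "target_sensitivity": 0.8},
}
issues = validate_config(config)
print("config issues:", issues or "none")

outdir = run_pipeline(config, outdir=Path("scratch") / "example_run")
print((outdir / "summary.txt").read_text())
manifest = json.loads((outdir / "manifest.json").read_text())
print("outputs:", ", ".join(sorted(manifest["outputs"])))
# Rerunning with the same config and seed reproduces each of these files
# byte for byte (compare the manifest digests).
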