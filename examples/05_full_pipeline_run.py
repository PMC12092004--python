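"""One-call pipeline run from a JSON-style configuration.

`run_pipeline` takes a single config covering every stage (scene or input
files, segmentation knobs, subtype rules), writes the vesicle table,
neuron profiles, IR partitions and a provenance record to an output
directory, and is byte-for-byte reproducible given its seeds.
"""

import json
from pathlib import Path

from avhue import config_from_json, run_pipeline

config = config_from_json(
    {
        "mode": "synthetic",
        "scene": {"n_neurons": 10, "rng_seed": 5},
        "ir": {"n_objects": 60, "assoc_fraction": 0.5, "rng_seed": 6},
        "segmentation": {"thresholds_n_sample": 10},
    }
)

out = Path("scratch/example_run")
result = run_pipeline(config, out)

print("wrote:", sorted(p.name for p in out.iterdir() if p.is_file()))
print(f"vesicles detected: {len(result['vesicles'])}")
print("\nper-neuron profiles:")
print(result["profiles_frame"][["neuron_id", "AP", "AL", "PA_AL", "LY", "total"]])
print("\nprovenance:")
print(json.dumps({k: result["provenance"][k] for k in ("config_hash", "seeds", "n_vesicles")}, indent=2))
# Re-running with the same config reproduces every output file exactly;
# the provenance block records the config hash, seeds and effective
# classification rules used.
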