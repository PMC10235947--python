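"""One-config end-to-end run with a reproducibility manifest.

Synthesizes a study-shaped dataset and meta-analyzes it in a single
``run_all`` invocation; every output is a pure function of the config
and seed, and the manifest written next to the outputs records the
derived per-stage seeds so any stage can be rerun in isolation.
"""

import tempfile
from pathlib import Path

import pandas as pd
import yaml

from repskew import RunConfig, run

out_dir = Path(tempfile.mkdtemp()) / "demo_run"
cfg = RunConfig(
    command="run_all",
    out_dir=str(out_dir),
    seed=11,
    meta={"grouping": "taxon", "outcome": "M_star_sexdiff"},
)
outputs = run(cfg)
print("outputs:", sorted(outputs.values()))

summaries = pd.read_csv(out_dir / outputs["summaries"])
print(summaries.round(3).to_string(index=False))

manifest = yaml.safe_load((out_dir / "manifest.yaml").read_text())
print("\nper-stage seeds from the manifest:", manifest["stage_seeds"])
# rerunning with the same config reproduces these files byte for byte.
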