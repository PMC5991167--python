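"""Shared configuration for the analysis drivers.

One fixed seed, study-scale defaults (41 F6 lines, 7 chromosomes, published
filter thresholds) and a common results directory. Stage outputs accumulate
under ``results/pipeline`` so later drivers can reload earlier tables.
"""

from pathlib import Path

from rilmap.pipeline import RunConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"  # small summary tables
PIPELINE_DIR = ROOT / "scratch" / "pipeline"  # bulky stage outputs (SAM, matrices)

CONFIG = RunConfig(seed=2018)
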