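"""Classify post-surgical attentional deficits and compute score deltas.

A subject is classified as having a cognitive deficit if ANY score at the
1-week assessment falls on the impaired side of its clinical cutoff
(strictly below for accuracy scores, strictly above for timed TMT scores);
score deltas are 3-month minus pre-surgery.
"""

import runpy
from pathlib import Path

import pandas as pd

from capdyn.pipeline import run_pipeline

cfg = runpy.run_path(Path(__file__).with_name("00_config.py"))["run_config"]()
out = run_pipeline(cfg, stages=["classify"])
flags = pd.read_csv(out / "deficit_flags.csv")
print(f"deficit at 1 week: {int(flags['deficit'].sum())}/{len(flags)} subjects")
print(flags.drop(columns=["timepoint"]).set_index("subject").sum())
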