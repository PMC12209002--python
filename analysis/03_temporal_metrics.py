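"""Compute temporal metrics of the recovered state sequences.

Per subject, session and state: occurrence, mean duration, resilience
(self-transition probability), IN-/OUT-degree (shares of between-state
switches) and betweenness on the -log-probability transition graph, plus
the 3-month-minus-pre longitudinal deltas.
"""

import runpy
from pathlib import Path

import pandas as pd

from capdyn.pipeline import run_pipeline

cfg = runpy.run_path(Path(__file__).with_name("00_config.py"))["run_config"]()
out = run_pipeline(cfg, stages=["metrics"])
metrics = pd.read_csv(out / "metrics.csv")
caps_only = metrics[metrics["state"] > 0]
print("cohort mean metrics per CAP state:")
print(caps_only.groupby("state")[["occurrence", "duration", "resilience",
                                  "in_degree", "out_degree"]].mean().round(3))
delta = pd.read_csv(out / "metrics_delta.csv")
print(f"longitudinal deltas written for {delta['subject'].nunique()} subjects")
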