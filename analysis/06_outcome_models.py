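"""Predict attention outcomes from presurgical FPN dynamics (Models 1-5).

Model 1: random-intercept mixed model of longitudinal TMT-B on deficit
status, timepoint, FPN metrics and deficit x time interactions.  Models
2-3: logistic models of 1-week deficit on presurgical transition
(OUT-degree) and stability (occurrence, resilience) properties.  Models
4-5: linear models of 1-week scores on presurgical degrees.  Also exports
the degree-vs-score scatter data per deficit group.
"""

import runpy
from pathlib import Path

import pandas as pd

from capdyn.pipeline import run_pipeline

cfg = runpy.run_path(Path(__file__).with_name("00_config.py"))["run_config"]()
out = run_pipeline(cfg, stages=["predict"])
coefs = pd.read_csv(out / "model_coefficients.csv")
sig = coefs[(coefs["p_value"] < 0.05) & (coefs["term"] != "intercept")]
print("significant terms (p < 0.05):")
print(sig[["model", "response", "term", "estimate", "p_value"]].round(4).to_string(index=False))
print(f"scatter data for degree-vs-score panels: {out / 'fig3_scatter.csv'}")
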