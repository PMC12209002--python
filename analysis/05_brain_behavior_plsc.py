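"""Grouped behavioral PLSC of FPN dynamics changes vs score changes.

Brain block: 3-month-minus-pre changes in the FPN-like CAP's occurrence,
duration, resilience and degrees.  Behavior block: score deltas.  Blocks
are z-scored within deficit group, cross-correlations stacked per group
and decomposed by SVD; latent-component significance comes from 1000
within-group permutations and salience stability from 500 within-group
bootstrap resamples (5th-95th percentile intervals).
"""

import json
import runpy
from pathlib import Path

from capdyn.pipeline import run_pipeline

cfg = runpy.run_path(Path(__file__).with_name("00_config.py"))["run_config"]()
out = run_pipeline(cfg, stages=["plsc"])
plsc = json.loads((out / "plsc.json").read_text())
sig = [i + 1 for i, p in enumerate(plsc["perm_p"]) if p < 0.05]
print("singular values:", [round(s, 3) for s in plsc["singular_values"]])
print("permutation p:  ", [round(p, 4) for p in plsc["perm_p"]])
print(f"significant latent components at alpha=0.05: {sig or 'none'}")
if sig:
    lc = sig[0] - 1
    robust = [plsc["brain_columns"][j]
              for j in range(len(plsc["brain_columns"]))
              if plsc["robust_brain"][j][lc]]
    print(f"bootstrap-robust brain saliences on LC{sig[0]}: {robust}")
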