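"""Generate the synthetic longitudinal glioma cohort.

22 subjects x 2 fMRI sessions (pre-surgery, 3-month post), 180 frames x 90
parcels per run, emitted from a hidden Markov chain over four co-activation
states plus a noise-only baseline.  Half the subjects form a "deficit"
group whose FPN-like state is less stable and more switched-into, and
whose 1-week behavioral scores are shifted past the clinical cutoffs.
Writes time series, manifest, behavior, seed definitions and full ground
truth under results/run/.
"""

import runpy
from pathlib import Path

from capdyn.pipeline import run_pipeline

cfg = runpy.run_path(Path(__file__).with_name("00_config.py"))["run_config"]()
run_pipeline(cfg, stages=["simulate"])
print(f"cohort written to {cfg.outdir}: 44 subject-session time series, "
      "behavior at pre/1w/3m, ground truth retained for recovery checks")
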