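"""Shared configuration for the analysis drivers.

All drivers write into one run directory under results/ and share a single
RNG seed, so the whole analysis is reproducible end to end (rerunning any
driver with the same upstream artifacts is bit-identical).
"""

import logging
import sys

from capdyn.config import RunConfig


def run_config() -> RunConfig:
    logging.basicConfig(
        stream=sys.stderr, level=logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
    return RunConfig(outdir="results/run", rng_seed=1)
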