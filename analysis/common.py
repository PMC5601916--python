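"""Shared setup for the numbered analysis drivers.

Each driver runs one pipeline stage on the default study configuration in a
persistent run directory (scratch/run), so the scripts can be executed in
order 01..06 and each picks up the previous stage's outputs. Small summary
tables land under results/.
"""

from __future__ import annotations

import argparse
import logging
import sys
from pathlib import Path

from corepressor_map.config import PipelineConfig, load_config

RESULTS = Path("results")


def setup(description: str) -> PipelineConfig:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--config", default=None, help="YAML pipeline config")
    parser.add_argument("--outdir", default="scratch/run",
                        help="run directory shared by all stages")
    parser.add_argument("--seed", type=int, default=None)
    args = parser.parse_args()
    cfg = load_config(args.config) if args.config else PipelineConfig()
    cfg.outdir = args.outdir
    if args.seed is not None:
        cfg.sim.seed = args.seed
    logging.basicConfig(level=logging.INFO, stream=sys.stderr,
                        format="%(levelname)s %(name)s: %(message)s")
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    return cfg
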