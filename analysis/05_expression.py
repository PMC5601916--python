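#!/usr/bin/env python
"""Differential expression (log2-CPM + Welch t) in the two perturbations,
the 1.7-fold / P<0.05 gate, and coregulation calling by direction agreement
with a Fisher exact overlap test."""

import json
import shutil
from pathlib import Path

from common import setup, RESULTS
from corepressor_map.pipeline import run_all
from corepressor_map.ioutils import read_tsv

cfg = setup(__doc__)
run_all(cfg, stages=["expression"])

outdir = Path(cfg.outdir)
summary = json.loads((outdir / "coregulation.json").read_text())
de_a = read_tsv(outdir / "de_A.tsv")
de_b = read_tsv(outdir / "de_B.tsv")

print(f"perturbation A: {int(de_a['passes'].sum())} genes pass the gate; "
      f"perturbation B: {int(de_b['passes'].sum())}")
print(f"coregulated: {summary['n_correlated']} correlated, "
      f"{summary['n_anti_correlated']} anti-correlated "
      f"(overlap Fisher P = {summary['overlap_p']:.2e}, "
      f"odds = {summary['overlap_odds']:.1f})")

shutil.copy(outdir / "coregulation.json", RESULTS / "coregulation.json")
print(f"wrote {RESULTS/'coregulation.json'}")
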