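#!/usr/bin/env python
"""Cistrome algebra: rpm/input filtering, reciprocal-overlap co-binding of
factors A and B, intersection with the knockout-filtered factor-C cistrome,
and 2-fold knockout-dependency calls."""

import json
import shutil
from pathlib import Path

from common import setup, RESULTS
from corepressor_map.pipeline import run_all
from corepressor_map.ioutils import read_tsv

cfg = setup(__doc__)
run_all(cfg, stages=["cistrome"])

outdir = Path(cfg.outdir)
venn = json.loads((outdir / "venn.json").read_text())
triple = json.loads((outdir / "triple.json").read_text())
corr = json.loads((outdir / "correlation.json").read_text())
dep = read_tsv(outdir / "dependency.tsv")

print(f"overlap partition: {venn['co_bound']} co-bound, "
      f"{venn['a_only']} A-only, {venn['b_only']} B-only")
print("factor-C overlap by class: "
      + ", ".join(f"{k}={v:.1%}" for k, v in triple["fractions"].items()))
print(f"co-bound vs A-only chi2 P = "
      f"{triple['tests']['co_bound_vs_a_only']['p']:.2e}")
lost = (dep["status"] == "lost").groupby(dep["factor"]).sum()
print(f"peaks lost (>= {cfg.thresholds.dependency_fold:g}-fold decrease) in "
      f"the C-knockout: " + ", ".join(f"{f}: {n}" for f, n in lost.items()))
print(f"A~B signal correlation over the union peak set: "
      f"r = {corr['pearson_r']:.3f}")

for name in ("venn.json", "triple.json"):
    shutil.copy(outdir / name, RESULTS / name)
print(f"wrote {RESULTS/'venn.json'}, {RESULTS/'triple.json'}")
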