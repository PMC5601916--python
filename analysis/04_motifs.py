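#!/usr/bin/env python
"""Scan 200 bp peak windows with the built-in DR1 (HNF4a-like), DR2
(Rev-erb-like) and C/EBP-like PWMs and compare motif frequencies between the
co-bound and single-factor peak classes by Pearson chi-square."""

import shutil
from pathlib import Path

from common import setup, RESULTS
from corepressor_map.pipeline import run_all
from corepressor_map.ioutils import read_tsv

cfg = setup(__doc__)
run_all(cfg, stages=["motifs"])

outdir = Path(cfg.outdir)
freq = read_tsv(outdir / "motif_freq.tsv")
comp = read_tsv(outdir / "motif_compare.tsv")

print("motif frequency by peak class:")
print(freq.pivot(index="pwm", columns="class", values="fraction")
      .round(3).to_string())
print("\nclass comparisons (chi2):")
print(comp.to_string(index=False))

shutil.copy(outdir / "motif_freq.tsv", RESULTS / "motif_freq.tsv")
shutil.copy(outdir / "motif_compare.tsv", RESULTS / "motif_compare.tsv")
print(f"\nwrote {RESULTS/'motif_freq.tsv'}, {RESULTS/'motif_compare.tsv'}")
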