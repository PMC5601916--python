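#!/usr/bin/env python
"""Score the ChIP-MS interactome: iBAQ quantification, median normalization,
downshifted-Gaussian imputation, bait-vs-control t-tests, the 10-fold /
P<0.01 interactor gate, and Benzonase-based direct vs DNA-bridged classes."""

from pathlib import Path

from common import setup, RESULTS
from corepressor_map.pipeline import run_all
from corepressor_map.ioutils import read_tsv, write_tsv

cfg = setup(__doc__)
run_all(cfg, stages=["interactome"])

table = read_tsv(Path(cfg.outdir) / "interactome.tsv")
hits = table[table["is_interactor"]].sort_values(
    "log2_enrichment", ascending=False
)
print(f"{len(hits)} interactors pass the "
      f"{cfg.thresholds.interactor_fold:g}-fold / "
      f"P<{cfg.thresholds.interactor_p:g} gate "
      f"(of {len(table)} quantified proteins)")
print(hits["nuclease_class"].value_counts().to_string())

write_tsv(hits.head(25), RESULTS / "interactome_top25.tsv")
print(f"wrote {RESULTS/'interactome_top25.tsv'}")
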