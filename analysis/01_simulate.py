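#!/usr/bin/env python
"""Generate the synthetic multi-omic study: ChIP-MS peptide intensities with
spiked interactors, three-factor cistromes on a toy genome, and a
two-perturbation expression matrix, plus ground-truth labels."""

import json
from pathlib import Path

from common import setup
from corepressor_map.pipeline import run_all
from corepressor_map.ioutils import read_tsv

cfg = setup(__doc__)
run_all(cfg, stages=["simulate"])

outdir = Path(cfg.outdir)
peptides = read_tsv(outdir / "peptides.tsv")
truth = json.loads((outdir / "truth.json").read_text())
genes = read_tsv(outdir / "genes.tsv")

print(f"simulated {cfg.sim.n_proteins} proteins -> "
      f"{len(peptides):,} observed peptide intensities "
      f"({peptides['sample_id'].nunique()} IP samples, 3 nuclease strata)")
print(f"spiked {len(truth['true_interactors'])} true interactors "
      f"({len(truth['dna_bridged'])} DNA-bridged)")
print(f"planted {len(truth['planted_cobound'])} co-bound peaks, "
      f"{len(truth['dependent_peaks'])} knockout-dependent")
print(f"{len(genes)} gene models; {len(truth['coregulated_genes'])} genes "
      f"planted co-upregulated near dependent sites")
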