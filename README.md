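# corepressor-map

Multi-omic inference chain for mapping a corepressor module: how a
deacetylase–transcription-factor pair (an HDAC3–PROX1-like module) is
recruited to chromatin by a DNA-binding factor (HNF4α-like), and how losing
any member of the hierarchy de-represses the same target genes.

The package implements, as a tested and reusable library plus an analysis
pipeline, the full chain of computations such a study runs:

1. **ChIP-MS interactome scoring** — peptide intensities from cross-linked
   bait vs control IPs are collapsed to protein iBAQ values
   (`iBAQ = Σ peptide intensity / # theoretical tryptic peptides`),
   log2-transformed, median-centered per sample, missing values imputed from
   a downshifted Gaussian `N(μ − 2σ, (0.25σ)²)` per sample, and enrichment
   tested with a two-tailed homoscedastic t-test. Interactors pass a 10-fold /
   P < 0.01 gate; interactions whose enrichment collapses below 8-fold after
   promiscuous (Benzonase) nuclease treatment are classified DNA-bridged
   rather than direct.
2. **Cistrome algebra** — peaks are quantified as rpm (reads per million),
   filtered at > 3× input and per-factor rpm floors (2 / 1.5 rpm), co-binding
   is called by ≥ 50% reciprocal overlap with ≥ 1 rpm of the other factor,
   a third cistrome is intersected with each peak class, and knockout
   dependency is a pseudocounted fold-decrease
   `(rpm_ctl + 0.1)/(rpm_KO + 0.1) ≥ 2`.
3. **Motif enrichment** — 200 bp windows on peak midpoints are scanned with
   log-odds PWMs (both strands); class frequencies are compared by Pearson χ².
4. **Expression coregulation** — log2-CPM + Welch t per perturbation, the
   1.7-fold / P < 0.05 gate, and splitting of double-passers into correlated /
   anti-correlated sets with a Fisher exact overlap test.
5. **Cross-omic association** — dependent co-bound sites are linked to genes
   (nearest TSS within 100 kb, or the strand-aware window TSS − 50 kb through
   TES + 2 kb) and the 2×2 gene table (has dependent site × coregulated) is
   tested with a Yates-corrected χ². Rank-sum and one-tailed t helpers cover
   binding-strength and sequential-ChIP comparisons.

Because the analyses only make sense on data with known answers, the package
ships a seeded synthetic-data generator (`corepressor_map.synthetic`) that
emulates the study design — spiked true interactors with
missing-not-at-random dropout, motif-nucleated co-bound peaks that collapse
in a knockout, genes near dependent sites planted as co-upregulated — and
every stage is benchmarked against that ground truth.

## Worked example

The numbered drivers under `analysis/` run the default study
(2,000 proteins with 50 interactors spiked 16-fold in 11 bait vs 13 control
IPs; 400 peaks per factor at read depth 50 collapsing 4-fold in the
knockout; 1,000 genes with coupling probability 0.6) into `scratch/run/`:

```sh
python analysis/01_simulate.py
python analysis/02_interactome.py
python analysis/03_cistrome.py
python analysis/04_motifs.py
python analysis/05_expression.py
python analysis/06_integrate.py
```

Output of `02`–`06` (seed 0):

```
50 interactors pass the 10-fold / P<0.01 gate (of 2000 quantified proteins)
direct         35
dna_bridged    15

overlap partition: 111 co-bound, 258 A-only, 273 B-only
factor-C overlap by class: a_only=0.4%, b_only=1.1%, co_bound=91.0%
co-bound vs A-only chi2 P = 3.03e-71

motif frequency by peak class:   a_only  b_only  co_bound
hnf4_dr1                          0.004   0.029     1.000
reverb_dr2                        0.996   0.004     0.018

coregulated: 38 correlated, 0 anti-correlated (overlap Fisher P = 1.27e-26)

association table (rows: has dependent link; cols: coregulated):
  [[36, 49], [2, 831]]  over 918 genes
Yates chi2 = 334.2, P = 1.17e-74
```

Reading the numbers: all 50 spiked interactors are recovered and the 15
DNA-bridged ones are correctly separated by the Benzonase criterion; factor C
binds 91% of co-bound peaks but almost no single-factor peaks (its DR1 motif
sits under co-bound peaks, the DR2 motif under A-only peaks); and genes
carrying a knockout-dependent co-bound site are overwhelmingly the ones
co-upregulated in both perturbations — the synthetic analogue of the
recruitment hierarchy the pipeline is designed to detect.

The same stages are exposed as a CLI
(`corepressor-map {simulate,interactome,cistrome,motifs,expression,integrate,run-all} --config cfg.yaml`),
which records a manifest of input/output SHA-256 hashes; identical
configurations reproduce identical manifests byte for byte.

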