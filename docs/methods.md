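# Methods

## The inference chain

The package models a three-layer recruitment hierarchy on chromatin: a
DNA-binding nucleating factor (C, HNF4α-like) recruits a corepressor module of
two factors (A, PROX1-like; B, HDAC3-like) to shared sites, and losing any
member de-represses the module's target genes. Five analyses, each usable on
its own, chain into the full inference:

**Interactome scoring.** Input is a post-identification peptide intensity
table from cross-linked bait vs control IPs, in three nuclease strata (none,
MNase, Benzonase). Protein abundance is iBAQ: summed observed peptide
intensity divided by the count of theoretically observable tryptic peptides
(in-silico digest: cleave C-terminal to K/R except before P, zero missed
cleavages, fragment length 6–30 — the conventional parameters; the study does
not state them, so they are exposed as arguments). Values are log2-transformed
and centered on each sample's observed median. Missing values are imputed per
sample from `N(μ − downshift·σ, (width·σ)²)` with width 0.25 and downshift
2.0 — the standard left-censored-missingness idiom, which presumes that
low-abundance measurements are preferentially missing. Enrichment is the mean
log2 difference bait − control with a two-tailed pooled-variance t-test,
tested on imputed values (the stated workflow imputes before testing);
Benjamini–Hochberg adjusted P-values are reported alongside the raw P used by
the volcano gate. Interactors require ≥ 10-fold enrichment and P < 0.01 (the
stricter of the two gates the source analysis quotes; both are parameters).
Each nuclease stratum is scored against its own controls. An untreated-stratum
interactor is *direct* if its Benzonase enrichment stays ≥ 8-fold,
*dna_bridged* if it falls below while the untreated enrichment met the 10-fold
gate, *indeterminate* if it is absent from the treated stratum. Proteins
observed in < 50% of samples of both arms are flagged, not dropped.

**Cistrome algebra.** Coordinates are 0-based half-open everywhere (native
BED); 1-based tables are converted at the boundary. Peak signal is
rpm = reads × 10⁶ / library size (browser RPTM = 10 × rpm). Filtering keeps
peaks with rpm above the per-factor floor (A: 2, B: 1.5, C: 2 rpm) and above
3 × (input rpm + 0.1); the 0.1 rpm pseudocount guards zero-input peaks. A
peak is co-bound when a partner peak overlaps ≥ 50% of *either* peak's length
(the source does not say whose length the fraction refers to, so the rule is
evaluated from both sides and either suffices) and the partner factor shows
≥ 1 rpm there. Because inputs are called peak sets — one read count per peak,
no base-pair coverage — the "other factor's signal at a peak" is the
overlapping partner peak's rpm; ties go to the maximally overlapping partner,
then to the lexicographically smaller id. Venn counts report co-bound A-side
peaks once each. The third cistrome is pre-filtered on the knockout: C peaks
whose KO rpm is ≥ 50% of control rpm are discarded as nonspecific before
intersecting (threshold exposed). Dependency is
`(rpm_ctl + 0.1)/(rpm_KO + 0.1) ≥ 2` over the fixed control peak interval
(rpm over the called interval, not a re-called peak height). Cistrome
correlation is Pearson r of the two factors' rpm over the merged union
intervals, apportioning each peak's rpm by its overlap with the interval.

**Motif comparison.** PWMs are scanned as log2-odds against the background
over 200 bp windows centered on peak midpoints, both strands; windows
containing N score −∞; windows clipped at chromosome ends are scanned with a
warning. The hit threshold defaults to 80% of a PWM's maximal score — scanner
thresholds are never published with figure-level enrichment claims, so only
planted synthetic structure is asserted, never absolute frequencies. Class
frequencies are compared with Pearson's χ² (no continuity correction, per the
source's stated convention for peak-class comparisons), switching to Fisher's
exact test with a warning when an expected cell drops below 1. Three toy PWMs
ship for the synthetic genome (DR1 nuclear-receptor repeat, DR2 repeat,
C/EBP-like palindrome); JASPAR-format files are accepted for real motifs.

**Expression and coregulation.** The differential engine is deliberately a
documented stand-in — log2(CPM + 1) with library size = column sum, Welch t
per gene — because the contribution being reproduced is the gate and the
coregulation logic, not a dispersion-modeling DE engine; the engine is one
function and swappable. The gate is |fold| ≥ 1.7 (inclusive) and P < 0.05.
Genes passing in both perturbations split by sign agreement into correlated /
anti-correlated; overlap significance is Fisher's exact test on the
pass/fail × perturbation table (the source names no test here; Fisher is this
package's choice). Zero-variance genes with equal means get P = 1.

**Integration.** Peak-to-gene links use two conventions: nearest TSS by
|peak midpoint − TSS| within 100 kb (ties to the lexicographically smaller
gene id), and containment of the midpoint in the strand-aware window
[TSS − 50 kb, TES + 2 kb], closed at both boundaries, multi-gene links
allowed. The association universe is coregulated genes plus *unchanged* genes
(failing the gate in both perturbations); genes changed in exactly one
perturbation are ambiguous and excluded, and anti-correlated genes count as
coregulated only behind a flag (the claim under test concerns co-regulated,
predominantly co-upregulated, targets). The 2×2 table (has dependent co-bound
link × coregulated) is tested with a Yates-corrected χ², which errors on a
degenerate margin. Binding-strength comparisons use a two-sided Mann–Whitney
U — exact for combined n ≤ 20 without ties, normal approximation with tie
correction otherwise, P = 1 when everything is tied; sequential-ChIP signal
uses a one-tailed (greater) pooled-variance t-test.

## The synthetic benchmark

The generator (`corepressor_map.synthetic`) is a pure function of its
`SimConfig`: identical configs give bit-identical outputs; all streams derive
from `default_rng([seed, stream])`.

*Proteomics.* Random 120–600-residue protein sequences (regenerated if the
digest yields no 6–30-mer); per-protein log2 abundance `N(20, 2²)` (arbitrary
intensity scale ~10⁶), per-peptide ionization offset `N(0, 1)`, per-observation
noise `N(0, 0.8²)`. True interactors gain log2(16) in bait samples; bridged
interactors lose the gain in the Benzonase stratum only. Dropout is MNAR:
P(missing) = logistic(−1.2 · (log2 intensity − 17)), ≈ 15% overall, heavily
left-censored — matching the assumption behind downshifted-Gaussian
imputation. 11 bait vs 13 control samples per stratum, the study's design.

*Cistromes.* Two 25 Mb chromosomes; 400 loci per factor drawn without
replacement from a grid spaced 3 peak-widths apart (error if the genome cannot
host them without overlap). Every C locus carries the DR1 consensus; with
probability 0.3 it also receives co-bound A and B peaks (jittered ≤ ¼ width,
guaranteeing ≥ 50% mutual overlap); A-only loci carry the DR2 consensus,
B-only loci no motif. Reads are Poisson with mean 50 × a per-locus lognormal
strength (σ = 0.5 ln-scale) shared by co-bound peaks — giving realistic
signal dynamic range and a positive co-bound signal correlation; inputs at
10% depth. In the C-knockout, C peaks collapse to 5% depth (5% of C peaks
persist as planted artifacts for the KO-persistence filter) and co-bound A/B
peaks — the *dependent* truth set — divide by 4.

*Expression.* Gene models tile the genome (~50 kb spacing, 2–10 kb lengths,
random strand). Baseline negative-binomial means are lognormal
(ln-mean 5, ln-SD 1, i.e. median ≈ 150 counts), dispersion 0.05. Genes linked
to truth dependent sites by the TSS−50k/TES+2k window are planted as
co-upregulated 3-fold in both knockout/knockdown arms with probability 0.6;
arms are 2/3/3/3 samples, the study's design. The planted 3-fold default
reflects a power analysis: with a t-test engine at n = 3 per arm, the
1.7-fold gate caps per-arm sensitivity near 0.8 for a 3-fold effect and far
lower for 2-fold, so a smaller default would make the benchmark's
coregulation layer mostly noise.

What the generator does **not** emulate: read-level data (peaks arrive
pre-called with one count each — no sub-peak structure, no peak-calling
errors), genome composition (uniform base frequencies outside planted
motifs), peptide identification (no FDR machinery, no razor peptides),
library-composition effects beyond CPM, and correlated biological replicates.
Passing tests therefore demonstrate that the *analysis chain* is correct and
calibrated on data satisfying its assumptions — not that those assumptions
hold on any particular real dataset.

## Calibration and validation design

Each calibration replicate contributes one P-value or one call, so the 500
replicates are independent. Continuous tests (interactome t, Welch DE t) are
checked for uniformity by Kolmogorov–Smirnov; Pearson χ² (mildly discrete)
with a two-sided binomial check of the rejection rate at α = 0.05; Fisher's
exact test and the Yates χ² are conservative by construction, so their
appropriate type-I-error check is one-sided — the rejection rate must not
exceed the 99.9% binomial bound. The interactor *call* under the null keeps
only positive enrichment, so its nominal rate is α/2. The interactome null
uses negligible missingness (midpoint far below the abundance range) so that
the t-test's normality assumption is exact and the check isolates the test
machinery; MNAR + imputation bias is a property of the imputation idiom, not
a defect detectable under the null. End-to-end with coupling 0, zero genes
may pass both gates, which makes the association table degenerate: that
outcome counts as a non-rejection.

Problem sizes used by the test suite and the acceptance script — the full
default study for recovery (2,000 proteins, 800 peaks, 1,000 genes; 20 seeds
for the association rejection rate), 50–60 entities per replicate for the
500-replicate null calibrations, and ≤ 30-interval instances for the 100-fold
brute-force oracle comparisons — were chosen to make the whole suite a
few-minute run while keeping every binomial check adequately powered.

## Numerical conventions and degenerate inputs

Identical values in both arms of a t-test give t = 0, P = 1 (scipy returns
NaN; the package defines the no-evidence result). Fold-decrease ratios are
pseudocounted with 0.1 rpm so empty KO peaks stay finite. PWM probabilities
are floored at 1e-9 before log-odds. Samples with < 2 observed values cannot
be imputed (σ undefined) and error; samples with no observed values cannot be
normalized and error. BED intervals with start ≥ end error with file and
line. Peak-id sets must match exactly across knockout conditions. The
one-based conversion maps closed [1, 100] to half-open [0, 100).

## Known limitations

- The DE stand-in has no dispersion shrinkage; at n = 2–3 per arm its power
  against the 1.7-fold gate is modest (see above), which the benchmark's
  effect sizes acknowledge.
- Cross-factor signal at a peak is the partner peak's rpm, not re-quantified
  coverage; with called-peak inputs nothing finer exists.
- Motif hit frequencies are threshold-dependent; only class *contrasts* are
  meaningful.
- The union-interval correlation between two cistromes that share only a
  minority of sites is dominated by single-factor intervals and can be
  negative; the co-bound-subset correlation is the informative summary for a
  shared-occupancy claim.
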