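"""Configuration objects for the synthetic benchmark and the analysis pipeline.

All thresholds used by the analysis stages are named keys with the published
defaults (10-fold / P 0.01 interactor gate, 8-fold Benzonase retention,
3-fold-over-input and 2 / 1.5 rpm peak filters, 50% reciprocal overlap with
1 rpm cross-factor signal, 2-fold knockout dependency, 1.7-fold / P 0.05
differential-expression gate, 100 kb nearest-gene and −50 kb TSS / +2 kb TES
windows, 200 bp motif windows).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml


@dataclass
class SimConfig:
    """Parameters of the synthetic multi-omic data generator.

    The defaults define the benchmark's study conditions: a cross-linked
    ChIP-MS experiment with 11 bait vs 13 control IPs per nuclease stratum and
    50 spiked true interactors (16-fold) among 2,000 proteins, of which 15 are
    DNA-bridged (their enrichment collapses under promiscuous nuclease); three
    transcription-factor cistromes on a toy two-chromosome genome where
    factor-C motifs nucleate A+B co-bound peaks that collapse 4-fold in a
    C-knockout; and an expression matrix where genes adjacent to dependent
    co-bound sites are preferentially co-upregulated upon loss of A or B.
    """

    seed: int = 0

    # --- proteomics ---
    n_proteins: int = 2000
    n_true_interactors: int = 50
    n_dna_bridged: int = 15
    interactor_effect: float = 16.0          # linear fold bait/control
    missingness_steepness: float = 1.2       # logistic MNAR slope on log2 intensity
    missingness_midpoint: float = 17.0       # log2 intensity of 50% missingness
    n_bait_samples: int = 11
    n_control_samples: int = 13
    protein_log2_mean: float = 20.0          # mean log2 abundance across proteins
    protein_log2_sd: float = 2.0
    peptide_log2_sd: float = 0.8             # per-observation measurement noise
    protein_length_range: tuple[int, int] = (120, 600)

    # --- cistromes ---
    genome: Sequence[tuple[str, int]] = (("chr1", 25_000_000), ("chr2", 25_000_000))
    n_peaks_per_factor: int = 400
    peak_width: int = 200
    frac_cobound: float = 0.3                # A/B peaks planted at shared C loci
    dependency_effect: float = 4.0           # fold collapse of dependent peaks in C-KO
    read_depth: float = 50.0                 # mean reads per peak
    peak_strength_sigma: float = 0.5         # ln-scale SD of per-locus occupancy;
                                             # co-bound peaks share their locus strength
    input_depth_frac: float = 0.1            # input reads as fraction of read_depth
    background_depth_frac: float = 0.05      # residual KO signal at collapsed C peaks
    nonspecific_frac: float = 0.05           # C peaks persisting in the C-KO (artifacts)
    chip_library_size: int = 10_000_000

    # --- expression ---
    n_genes: int = 1000
    coupling_pi: float = 0.6                 # P(linked gene planted co-upregulated)
    de_effect: float = 3.0                   # linear fold-change of planted genes
    dispersion: float = 0.05                 # negative-binomial dispersion
    gene_length_range: tuple[int, int] = (2000, 10_000)
    base_expression_log_mean: float = 5.0    # ln-scale mean of baseline NB means
    base_expression_log_sd: float = 1.0
    n_control_a: int = 2
    n_ko_a: int = 3
    n_control_b: int = 3
    n_kd_b: int = 3

    def validate(self) -> None:
        counts = {
            "n_proteins": self.n_proteins,
            "n_true_interactors": self.n_true_interactors,
            "n_bait_samples": self.n_bait_samples,
            "n_control_samples": self.n_control_samples,
            "n_peaks_per_factor": self.n_peaks_per_factor,
            "peak_width": self.peak_width,
            "n_genes": self.n_genes,
            "n_control_a": self.n_control_a,
            "n_ko_a": self.n_ko_a,
            "n_control_b": self.n_control_b,
            "n_kd_b": self.n_kd_b,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if self.n_dna_bridged < 0:
            raise ValueError("n_dna_bridged must be >= 0")
        if self.n_true_interactors > self.n_proteins:
            raise ValueError(
                f"n_true_interactors ({self.n_true_interactors}) exceeds "
                f"n_proteins ({self.n_proteins})"
            )
        if self.n_dna_bridged > self.n_true_interactors:
            raise ValueError("n_dna_bridged must be <= n_true_interactors")
        for name in ("frac_cobound", "coupling_pi", "nonspecific_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("interactor_effect", "dependency_effect", "de_effect",
                     "read_depth", "dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.genome:
            raise ValueError("genome must list at least one chromosome")
        for chrom, length in self.genome:
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["genome"] = [list(g) for g in self.genome]
        d["protein_length_range"] = list(self.protein_length_range)
        d["gene_length_range"] = list(self.gene_length_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "genome" in d:
            d["genome"] = tuple((str(c), int(n)) for c, n in d["genome"])
        for key in ("protein_length_range", "gene_length_range"):
            if key in d:
                d[key] = tuple(int(x) for x in d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class Thresholds:
    """Published analysis gates, one named key each."""

    interactor_fold: float = 10.0      # fold-enrichment cutoff for interactors
    interactor_p: float = 0.01         # P-value cutoff for interactors
    benzonase_fold: float = 8.0        # retention cutoff after Benzonase
    min_rpm_a: float = 2.0             # factor-A (PROX1-like) peak rpm floor
    min_rpm_b: float = 1.5             # factor-B (HDAC3-like) peak rpm floor
    min_rpm_c: float = 2.0             # factor-C (HNF4a-like) peak rpm floor
    input_fold: float = 3.0            # peak rpm must exceed input_fold x input rpm
    min_overlap_frac: float = 0.5      # reciprocal-overlap fraction for co-binding
    min_other_rpm: float = 1.0         # cross-factor signal floor at co-bound peaks
    dependency_fold: float = 2.0       # knockout fold-decrease calling a peak lost
    rpm_pseudocount: float = 0.1       # pseudocount (rpm) in fold-decrease ratios
    ko_persist_frac: float = 0.5       # C peaks with KO rpm >= this fraction of
                                       # control rpm are discarded as nonspecific
    de_fold: float = 1.7               # differential-expression fold gate
    de_p: float = 0.05                 # differential-expression P gate
    nearest_max_dist: int = 100_000    # nearest-gene assignment radius (bp)
    window_upstream: int = 50_000      # TSS-upstream extent of the gene window (bp)
    window_downstream: int = 2_000     # TES-downstream extent of the gene window (bp)
    motif_window: int = 200            # scan window centered on peak midpoints (bp)
    motif_threshold_frac: float = 0.8  # log-odds hit threshold as fraction of max

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if self.interactor_fold <= 0:
            raise ValueError("interactor_fold must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Thresholds":
        t = cls(**d)
        t.validate()
        return t


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    outdir: str = "scratch/run"
    impute_width: float = 0.25
    impute_downshift: float = 2.0

    def validate(self) -> None:
        self.sim.validate()
        self.thresholds.validate()
        if self.impute_width < 0:
            raise ValueError("impute_width must be >= 0")

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "thresholds": self.thresholds.to_dict(),
            "outdir": self.outdir,
            "impute_width": self.impute_width,
            "impute_downshift": self.impute_downshift,
        }


_KNOWN_TOP_KEYS = {"sim", "thresholds", "outdir", "impute_width", "impute_downshift"}


def load_config(path: str) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    Unknown keys raise, naming the offending field.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _KNOWN_TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    try:
        sim = SimConfig.from_dict(raw.get("sim", {}))
        thresholds = Thresholds.from_dict(raw.get("thresholds", {}))
    except TypeError as exc:
        raise ValueError(f"invalid config field: {exc}") from exc
    cfg = PipelineConfig(
        sim=sim,
        thresholds=thresholds,
        outdir=str(raw.get("outdir", "scratch/run")),
        impute_width=float(raw.get("impute_width", 0.25)),
        impute_downshift=float(raw.get("impute_downshift", 2.0)),
    )
    cfg.validate()
    return cfg


def dump_config(cfg: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
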