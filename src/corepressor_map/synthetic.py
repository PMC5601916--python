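"""Seeded synthetic multi-omic data with ground-truth labels.

The generator emulates the data structure the analysis assumes, not real
biology: (i) a cross-linked ChIP-MS experiment — log-normal peptide
intensities, spiked true interactors enriched in bait IPs (a subset
DNA-bridged, i.e. losing enrichment under promiscuous nuclease), and
missing-not-at-random dropout that is a logistic function of log2 intensity;
(ii) three factor cistromes on a toy genome where factor-C motif loci
nucleate A+B co-bound peaks that collapse in a C-knockout, with Poisson read
counts; (iii) a negative-binomial expression matrix where genes adjacent to
dependent co-bound sites are preferentially co-upregulated upon loss of A or
B. Every generator is a pure function of its SimConfig: identical configs
give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .expression import CountMatrix
from .cistrome import Cistrome, PEAK_COLUMNS
from .interactome import AMINO_ACIDS, digest_protein
from .motifs import builtin_pwms

NUCLEASE_STRATA = ("none", "mnase", "benzonase")


@dataclass
class SyntheticTruth:
    """Ground-truth labels for recovery testing."""

    true_interactors: set = field(default_factory=set)
    dna_bridged: set = field(default_factory=set)
    dependent_peaks: set = field(default_factory=set)
    planted_cobound: set = field(default_factory=set)
    coregulated_genes: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.dna_bridged <= self.true_interactors:
            raise ValueError("dna_bridged must be a subset of true_interactors")
        if not self.dependent_peaks <= self.planted_cobound | set():
            raise ValueError("dependent peaks must be planted co-bound peaks")

    def merged_with(self, other: "SyntheticTruth") -> "SyntheticTruth":
        return SyntheticTruth(
            self.true_interactors | other.true_interactors,
            self.dna_bridged | other.dna_bridged,
            self.dependent_peaks | other.dependent_peaks,
            self.planted_cobound | other.planted_cobound,
            self.coregulated_genes | other.coregulated_genes,
        )

    def to_json(self) -> str:
        return json.dumps(
            {k: sorted(v) for k, v in self.__dict__.items()}, indent=0, sort_keys=True
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(**{k: set(v) for k, v in d.items()})


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


# ---------------------------------------------------------------- proteomics

_AA_BYTES = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


def _random_proteins(rng: np.random.Generator, lengths: np.ndarray) -> list[str]:
    chars = _AA_BYTES[rng.integers(0, len(_AA_BYTES), size=int(lengths.sum()))]
    bounds = np.cumsum(lengths)[:-1]
    return [seg.tobytes().decode("ascii") for seg in np.split(chars, bounds)]


def simulate_proteomics(cfg: SimConfig) -> tuple[pd.DataFrame, dict, SyntheticTruth]:
    """Generate a peptide intensity table, protein sequences, and truth labels.

    Returns (peptide table, {protein_id: sequence}, truth). The table has one
    row per OBSERVED peptide/sample pair (dropout removes rows); columns are
    protein_id, peptide, sample_id, condition, nuclease, intensity.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    ids = [f"P{i:04d}" for i in range(cfg.n_proteins)]

    lo, hi = cfg.protein_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_proteins)
    seqs = _random_proteins(rng, lengths)
    proteins: dict[str, str] = {}
    peptide_lists: dict[str, list[str]] = {}
    for pid, seq in zip(ids, seqs):
        peps = digest_protein(seq)
        while not peps:  # rare: no tryptic fragment in the length window
            seq = _random_proteins(rng, np.array([int(rng.integers(lo, hi + 1))]))[0]
            peps = digest_protein(seq)
        proteins[pid] = seq
        peptide_lists[pid] = peps

    chosen = rng.choice(np.array(ids), size=cfg.n_true_interactors, replace=False)
    true_set = set(chosen.tolist())
    bridged = set(
        rng.choice(chosen, size=cfg.n_dna_bridged, replace=False).tolist()
    )
    truth = SyntheticTruth(true_interactors=true_set, dna_bridged=bridged)

    samples = []
    for stratum in NUCLEASE_STRATA:
        samples += [
            (f"bait_{stratum}_{i+1:02d}", "bait", stratum)
            for i in range(cfg.n_bait_samples)
        ]
        samples += [
            (f"ctl_{stratum}_{i+1:02d}", "control", stratum)
            for i in range(cfg.n_control_samples)
        ]
    sample_ids = np.array([s[0] for s in samples])
    conditions = np.array([s[1] for s in samples])
    strata = np.array([s[2] for s in samples])

    # flatten peptides
    prot_of_pep, pep_seqs = [], []
    for pid in ids:
        for pep in peptide_lists[pid]:
            prot_of_pep.append(pid)
            pep_seqs.append(pep)
    prot_of_pep = np.array(prot_of_pep)
    pep_seqs = np.array(pep_seqs)
    n_pep, n_samp = len(pep_seqs), len(samples)

    base_prot = rng.normal(cfg.protein_log2_mean, cfg.protein_log2_sd, cfg.n_proteins)
    base_of_prot = dict(zip(ids, base_prot))
    pep_offset = rng.normal(0.0, 1.0, n_pep)  # per-peptide ionization efficiency
    base = np.array([base_of_prot[p] for p in prot_of_pep]) + pep_offset

    effect = np.log2(cfg.interactor_effect)
    is_true = np.isin(prot_of_pep, list(true_set))
    is_bridged = np.isin(prot_of_pep, list(bridged))
    log2 = base[:, None] + rng.normal(0.0, cfg.peptide_log2_sd, (n_pep, n_samp))
    bait_col = conditions == "bait"
    benz_col = strata == "benzonase"
    gain = is_true[:, None] & bait_col[None, :] & ~(
        is_bridged[:, None] & benz_col[None, :]
    )
    log2 = log2 + gain * effect

    # MNAR dropout: lower intensity -> more likely missing
    p_miss = 1.0 / (
        1.0 + np.exp(cfg.missingness_steepness * (log2 - cfg.missingness_midpoint))
    )
    observed = rng.random((n_pep, n_samp)) >= p_miss

    pi, si = np.nonzero(observed)
    table = pd.DataFrame(
        {
            "protein_id": prot_of_pep[pi],
            "peptide": pep_seqs[pi],
            "sample_id": sample_ids[si],
            "condition": conditions[si],
            "nuclease": strata[si],
            "intensity": np.exp2(log2[pi, si]),
        }
    )
    return table, proteins, truth


# ----------------------------------------------------------------- cistromes

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_genome(rng: np.random.Generator, genome) -> dict[str, str]:
    return {
        chrom: _BASE_BYTES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        for chrom, length in genome
    }


def _plant(seqs: dict[str, np.ndarray], chrom: str, pos: int, motif: str) -> None:
    arr = seqs[chrom]
    arr[pos : pos + len(motif)] = np.frombuffer(motif.encode(), dtype=np.uint8)


def simulate_cistromes(
    cfg: SimConfig, make_sequence: bool = True
) -> tuple[dict, dict | None, dict, SyntheticTruth]:
    """Generate A/B/C cistromes in control and C-knockout conditions.

    Factor-C loci carry a DR1-type (HNF4a-like) motif; with probability
    ``frac_cobound`` a locus also receives co-bound A and B peaks, which
    collapse ``dependency_effect``-fold in the C-knockout. A-only peaks sit at
    DR2-type loci, B-only peaks at motif-less loci. Read counts are Poisson
    with mean ``read_depth`` (inputs at ``input_depth_frac`` of that).

    Returns (cistromes, genome sequences or None, pwms, truth); cistrome keys
    are (factor, condition) with factor in {A, B, C} and condition in
    {control, ko}.
    """
    cfg.validate()
    rng = _rng(cfg, 2)
    w = cfg.peak_width
    margin, spacing = 10 * w, 3 * w

    n = cfg.n_peaks_per_factor
    cobound_mask = rng.random(n) < cfg.frac_cobound
    n_cobound = int(cobound_mask.sum())
    n_a_only = n - n_cobound
    n_b_only = n - n_cobound
    needed = n + n_a_only + n_b_only

    grid = []
    for chrom, length in cfg.genome:
        positions = np.arange(margin, length - margin - w, spacing)
        grid += [(chrom, int(p)) for p in positions]
    if needed > len(grid):
        raise ValueError(
            f"genome too small: need {needed} non-overlapping loci, "
            f"grid holds {len(grid)}"
        )
    loci_idx = rng.choice(len(grid), size=needed, replace=False)
    loci = [grid[i] for i in loci_idx]
    c_loci = loci[:n]
    a_only_loci = loci[n : n + n_a_only]
    b_only_loci = loci[n + n_a_only :]

    pwms = builtin_pwms()

    def jitter() -> int:
        return int(rng.integers(-w // 4, w // 4 + 1))

    def peak_rows(prefix, loci_list, offsets):
        rows = []
        for i, ((chrom, pos), off) in enumerate(zip(loci_list, offsets)):
            rows.append((f"{prefix}{i:04d}", chrom, pos + off, pos + off + w))
        return rows

    c_rows = peak_rows("C", c_loci, [0] * n)
    cob_idx = np.flatnonzero(cobound_mask)
    a_rows = peak_rows("A", [c_loci[i] for i in cob_idx], [jitter() for _ in cob_idx])
    a_rows += [
        (f"A{len(cob_idx)+i:04d}", chrom, pos, pos + w)
        for i, (chrom, pos) in enumerate(a_only_loci)
    ]
    b_rows = peak_rows("B", [c_loci[i] for i in cob_idx], [jitter() for _ in cob_idx])
    b_rows += [
        (f"B{len(cob_idx)+i:04d}", chrom, pos, pos + w)
        for i, (chrom, pos) in enumerate(b_only_loci)
    ]

    cobound_a = {r[0] for r in a_rows[: len(cob_idx)]}
    cobound_b = {r[0] for r in b_rows[: len(cob_idx)]}
    dependent = (
        cobound_a | cobound_b if cfg.dependency_effect > 1.0 else set()
    )
    truth = SyntheticTruth(
        dependent_peaks=dependent, planted_cobound=cobound_a | cobound_b
    )

    depth, in_depth = cfg.read_depth, cfg.read_depth * cfg.input_depth_frac
    bg_frac = cfg.background_depth_frac
    nonspecific = rng.random(n) < cfg.nonspecific_frac

    # per-locus occupancy: co-bound peaks share their nucleating locus' strength
    sigma = cfg.peak_strength_sigma
    c_strength = rng.lognormal(0.0, sigma, n)
    a_only_strength = rng.lognormal(0.0, sigma, n_a_only)
    b_only_strength = rng.lognormal(0.0, sigma, n_b_only)
    a_strength = np.concatenate([c_strength[cob_idx], a_only_strength])
    b_strength = np.concatenate([c_strength[cob_idx], b_only_strength])

    def make_cistrome(factor, rows, condition, means):
        df = pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end"])
        df["reads"] = rng.poisson(means)
        df["input_reads"] = rng.poisson(in_depth, size=len(df))
        return Cistrome(factor, condition, df[list(PEAK_COLUMNS)],
                        cfg.chip_library_size)

    cistromes = {}
    for factor, rows, strength in (
        ("A", a_rows, a_strength), ("B", b_rows, b_strength), ("C", c_rows, c_strength)
    ):
        ctl_means = depth * strength
        cistromes[(factor, "control")] = make_cistrome(
            factor, rows, "control", ctl_means
        )
        if factor == "C":
            ko_means = np.where(nonspecific, ctl_means, bg_frac * ctl_means)
        else:
            dep = np.array([r[0] in dependent for r in rows])
            ko_means = np.where(dep, ctl_means / cfg.dependency_effect, ctl_means)
        cistromes[(factor, "ko")] = make_cistrome(factor, rows, "ko", ko_means)

    genome_seqs = None
    if make_sequence:
        raw = {
            chrom: _BASE_BYTES[rng.integers(0, 4, size=length)].copy()
            for chrom, length in cfg.genome
        }
        dr1 = pwms["hnf4_dr1"].consensus()
        dr2 = pwms["reverb_dr2"].consensus()
        for chrom, pos in c_loci:
            _plant(raw, chrom, pos + w // 2 - len(dr1) // 2, dr1)
        for chrom, pos in a_only_loci:
            _plant(raw, chrom, pos + w // 2 - len(dr2) // 2, dr2)
        genome_seqs = {c: a.tobytes().decode("ascii") for c, a in raw.items()}

    return cistromes, genome_seqs, pwms, truth


# ------------------------------------------------------------------- genes

def simulate_genes(cfg: SimConfig) -> pd.DataFrame:
    """Tile gene models over the toy genome (random lengths and strands)."""
    cfg.validate()
    rng = _rng(cfg, 4)
    total = sum(length for _, length in cfg.genome)
    rows = []
    gi = 0
    lo, hi = cfg.gene_length_range
    for chrom, length in cfg.genome:
        n_chrom = max(1, round(cfg.n_genes * length / total))
        if gi + n_chrom > cfg.n_genes:
            n_chrom = cfg.n_genes - gi
        spacing = length // (n_chrom + 1)
        for k in range(n_chrom):
            start = (k + 1) * spacing
            glen = int(rng.integers(lo, min(hi, max(lo + 1, spacing)) + 1))
            rows.append(
                (f"G{gi:04d}", chrom, start, min(start + glen, length - 1),
                 "+" if rng.random() < 0.5 else "-")
            )
            gi += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


# -------------------------------------------------------------- expression

def simulate_expression(
    cfg: SimConfig, genes: pd.DataFrame, linked_gene_ids
) -> tuple[CountMatrix, SyntheticTruth]:
    """Generate the two-perturbation count matrix.

    ``linked_gene_ids`` are genes adjacent to dependent co-bound sites (as
    produced by the peak-to-gene assignment on the truth dependent peaks);
    each is planted as co-upregulated (x de_effect in BOTH the KO_A and KD_B
    arms) with probability ``coupling_pi``.
    """
    cfg.validate()
    rng = _rng(cfg, 3)
    linked = sorted(set(linked_gene_ids) & set(genes["gene_id"]))
    if cfg.coupling_pi > 0 and not linked:
        raise ValueError("coupling_pi > 0 but the dependent-site link set is empty")

    gene_ids = genes["gene_id"].tolist()
    mu = np.exp(
        rng.normal(cfg.base_expression_log_mean, cfg.base_expression_log_sd,
                   len(gene_ids))
    )
    planted = [g for g in linked if rng.random() < cfg.coupling_pi]
    truth = SyntheticTruth(coregulated_genes=set(planted))

    sample_defs = (
        [(f"ctlA_{i+1}", "control_A") for i in range(cfg.n_control_a)]
        + [(f"koA_{i+1}", "KO_A") for i in range(cfg.n_ko_a)]
        + [(f"ctlB_{i+1}", "control_B") for i in range(cfg.n_control_b)]
        + [(f"kdB_{i+1}", "KD_B") for i in range(cfg.n_kd_b)]
    )
    sample_ids = [s for s, _ in sample_defs]
    conditions = np.array([c for _, c in sample_defs])

    means = np.tile(mu[:, None], (1, len(sample_ids)))
    planted_mask = np.isin(np.array(gene_ids), planted)
    up_cols = np.isin(conditions, ["KO_A", "KD_B"])
    means[np.ix_(planted_mask, up_cols)] *= cfg.de_effect

    r = 1.0 / cfg.dispersion
    p = r / (r + means)
    counts = rng.negative_binomial(r, p)
    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                     columns=sample_ids),
        pd.DataFrame({"condition": conditions}, index=pd.Index(sample_ids,
                                                               name="sample_id")),
    )
    return cm, truth
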