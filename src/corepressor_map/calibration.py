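"""Null calibration and planted-effect recovery benchmarks.

These routines drive the full analysis stages on generator output — they are
the package's own evidence that its significance calls are calibrated under
the null and that planted structure is recovered under the benchmark's study
conditions. Tests and the acceptance script both run them.

Calibration design: each replicate contributes one P-value (or one call), so
replicates are independent. Continuous tests (the homoscedastic interactome
t-test, the Welch expression t-test) are checked for uniformity; discrete
tests (Pearson chi-square) for a nominal rejection rate; Fisher's exact test
and the Yates-corrected chi-square are conservative by construction, so the
appropriate type-I-error check is one-sided (the rejection rate must not
exceed nominal).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimConfig, Thresholds
from .cistrome import classify_dependency
from .expression import call_coregulation, de_test
from .integration import assign_gene_window, association_test, build_gene_flags
from .interactome import (
    call_interactors,
    compute_ibaq,
    impute_missing,
    log2_median_normalize,
    test_enrichment,
    theoretical_peptide_counts,
)
from .synthetic import (
    simulate_cistromes,
    simulate_expression,
    simulate_genes,
    simulate_proteomics,
)

# small, fast study for per-replicate null calibration; the MNAR midpoint sits
# far below the abundance range so dropout is negligible and the t-test's
# normality assumption holds exactly
NULL_PROTEOMICS = SimConfig(
    n_proteins=60,
    n_true_interactors=1,
    n_dna_bridged=0,
    interactor_effect=1.0,
    n_bait_samples=5,
    n_control_samples=5,
    missingness_midpoint=5.0,
    protein_length_range=(80, 200),
)

NULL_EXPRESSION = SimConfig(
    coupling_pi=0.0,
    de_effect=1.0,
    n_genes=60,
    n_control_a=5,
    n_ko_a=5,
    n_control_b=5,
    n_kd_b=5,
)


def _sub_seed(seed: int, rep: int) -> int:
    return int((seed * 100003 + rep) % (2**31))


def _run_interactome_stratum(cfg: SimConfig, fold_cutoff=1.0, p_cutoff=0.05):
    peptides, proteins, truth = simulate_proteomics(cfg)
    sub = peptides[peptides["nuclease"] == "none"]
    digest = theoretical_peptide_counts(proteins)
    imp = impute_missing(
        log2_median_normalize(compute_ibaq(sub, digest)), seed=cfg.seed
    )
    res = test_enrichment(imp)
    return call_interactors(res, fold_cutoff, p_cutoff), truth


def null_interactome_pvalues(n_reps: int = 500, seed: int = 0) -> np.ndarray:
    """One enrichment P-value per replicate from a no-effect ChIP-MS study."""
    out = np.empty(n_reps)
    for r in range(n_reps):
        cfg = replace(NULL_PROTEOMICS, seed=_sub_seed(seed, r))
        res, _ = _run_interactome_stratum(cfg)
        out[r] = res["p_value"].iloc[0]
    return out


def null_interactor_call_rate(
    n_reps: int = 200, seed: int = 0, alpha: float = 0.05
) -> tuple[int, int]:
    """Interactor calls (fold gate disabled) vs trials under the null.

    With the fold cutoff at 1 the gate still requires positive enrichment, so
    the nominal call rate of the two-sided test is alpha/2.
    """
    calls = trials = 0
    for r in range(n_reps):
        cfg = replace(NULL_PROTEOMICS, seed=_sub_seed(seed, r))
        res, _ = _run_interactome_stratum(cfg, fold_cutoff=1.0, p_cutoff=alpha)
        calls += int(res["is_interactor"].iloc[0])
        trials += 1
    return calls, trials


def null_de_pvalues(n_reps: int = 500, seed: int = 0) -> np.ndarray:
    """One Welch P-value per replicate from a no-effect expression study."""
    out = np.empty(n_reps)
    genes = simulate_genes(NULL_EXPRESSION)
    for r in range(n_reps):
        cfg = replace(NULL_EXPRESSION, seed=_sub_seed(seed, r))
        cm, _ = simulate_expression(cfg, genes, set())
        out[r] = de_test(cm, "A")["p_value"].iloc[0]
    return out


def null_motif_chi2_rejections(
    n_reps: int = 500, seed: int = 0, alpha: float = 0.05,
    n_per_class: int = 60, window: int = 60,
) -> tuple[int, int]:
    """Pearson chi-square rejections comparing two null peak classes.

    Both classes are random windows from the same background, scanned with a
    short, permissive PWM so hit frequencies stay far from 0 and the 2x2
    chi-square is well behaved.
    """
    from .motifs import PWM, compare_motif_enrichment

    pwm = PWM("calib", np.tile([0.7, 0.1, 0.1, 0.1], (4, 1)), threshold_frac=0.8)
    rng_master = np.random.default_rng([seed, 77])
    rejections = trials = 0
    genome_len = 2 * n_per_class * window
    for _ in range(n_reps):
        codes = rng_master.integers(0, 4, size=genome_len)
        genome = {"chr1": "".join("ACGT"[c] for c in codes)}
        mids = np.arange(n_per_class * 2) * window + window // 2
        peaks = pd.DataFrame(
            {
                "peak_id": [f"p{i}" for i in range(2 * n_per_class)],
                "chrom": "chr1",
                "start": mids - window // 2,
                "end": mids + window // 2,
            }
        )
        res = compare_motif_enrichment(
            peaks.iloc[:n_per_class], peaks.iloc[n_per_class:], genome, pwm, window
        )
        if res["method"] == "pearson_chi2":
            rejections += int(res["p"] < alpha)
            trials += 1
    return rejections, trials


def null_coregulation_rejections(
    n_reps: int = 500, seed: int = 0, alpha: float = 0.05
) -> tuple[int, int]:
    """Fisher-exact overlap rejections with independent null perturbations.

    Pass flags are made common enough (permissive gate) that the 2x2 table is
    populated; Fisher remains valid at any gate.
    """
    genes = simulate_genes(NULL_EXPRESSION)
    rejections = 0
    for r in range(n_reps):
        cfg = replace(NULL_EXPRESSION, seed=_sub_seed(seed, r))
        cm, _ = simulate_expression(cfg, genes, set())
        de_a = de_test(cm, "A", fold=1.1, p_cutoff=0.3)
        de_b = de_test(cm, "B", fold=1.1, p_cutoff=0.3)
        coreg = call_coregulation(de_a, de_b)
        rejections += int(coreg.overlap_p < alpha)
    return rejections, n_reps


def null_association_rejections(
    n_reps: int = 500, seed: int = 0, alpha: float = 0.05,
    n_genes: int = 1000, rate_link: float = 0.25, rate_coreg: float = 0.2,
) -> tuple[int, int]:
    """Yates chi-square rejections on independent gene flags at fixed rates."""
    rng = np.random.default_rng([seed, 99])
    rejections = 0
    for _ in range(n_reps):
        flags = pd.DataFrame(
            {
                "gene_id": np.arange(n_genes),
                "has_dependent_link": rng.random(n_genes) < rate_link,
                "coregulated": rng.random(n_genes) < rate_coreg,
            }
        )
        res = association_test(flags)
        rejections += int(res.p < alpha)
    return rejections, n_reps


# ----------------------------------------------------------------- recovery

def interactor_recovery(cfg: SimConfig, thresholds: Thresholds | None = None) -> dict:
    """Sensitivity of interactor calling and accuracy of the nuclease classes
    under the benchmark conditions."""
    from .interactome import score_interactome

    t = thresholds or Thresholds()
    peptides, proteins, truth = simulate_proteomics(cfg)
    results = score_interactome(
        peptides, proteins,
        fold_cutoff=t.interactor_fold, p_cutoff=t.interactor_p,
        benzonase_fold=t.benzonase_fold, seed=cfg.seed,
    )
    untreated = results["none"]
    called = set(untreated.loc[untreated["is_interactor"], "protein_id"])
    sens = len(called & truth.true_interactors) / len(truth.true_interactors)
    false_calls = called - truth.true_interactors
    n_controls = cfg.n_proteins - cfg.n_true_interactors
    fpr = len(false_calls) / n_controls if n_controls else float("nan")

    classes = results["nuclease_classes"].set_index("protein_id")["nuclease_class"]
    evaluable = classes.index.intersection(sorted(truth.true_interactors))
    correct = sum(
        (classes.loc[p] == "dna_bridged") == (p in truth.dna_bridged)
        for p in evaluable
    )
    accuracy = correct / len(evaluable) if len(evaluable) else float("nan")
    return {
        "sensitivity": sens,
        "false_positive_rate": fpr,
        "n_called": len(called),
        "nuclease_accuracy": accuracy,
        "n_evaluable": int(len(evaluable)),
    }


def dependency_recovery(cfg: SimConfig, thresholds: Thresholds | None = None) -> dict:
    """Sensitivity/specificity of knockout-dependency calls vs planted truth."""
    t = thresholds or Thresholds()
    cistromes, _, _, truth = simulate_cistromes(cfg, make_sequence=False)
    calls = []
    for factor in ("A", "B"):
        calls.append(
            classify_dependency(
                cistromes[(factor, "control")],
                cistromes[(factor, "ko")],
                t.dependency_fold,
                t.rpm_pseudocount,
            )
        )
    calls = pd.concat(calls, ignore_index=True)
    lost = set(calls.loc[calls["status"] == "lost", "peak_id"])
    pos = truth.dependent_peaks
    neg = set(calls["peak_id"]) - pos
    sens = len(lost & pos) / len(pos) if pos else float("nan")
    specificity = len(neg - lost) / len(neg) if neg else float("nan")
    return {"sensitivity": sens, "specificity": specificity,
            "n_dependent": len(pos), "n_peaks": int(len(calls))}


def association_endtoend(
    cfg: SimConfig, thresholds: Thresholds | None = None
) -> dict:
    """One full cistrome->expression->association run; returns the Yates P.

    Dependency calls come from the analysis (not truth); genes linked to lost
    co-bound sites are tested against the coregulation calls.
    """
    t = thresholds or Thresholds()
    cistromes, _, _, truth = simulate_cistromes(cfg, make_sequence=False)
    genes = simulate_genes(cfg)

    dep_calls = []
    for factor in ("A", "B"):
        dep_calls.append(
            classify_dependency(
                cistromes[(factor, "control")],
                cistromes[(factor, "ko")],
                t.dependency_fold,
                t.rpm_pseudocount,
            )
        )
    dep_calls = pd.concat(dep_calls, ignore_index=True)
    lost = set(dep_calls.loc[dep_calls["status"] == "lost", "peak_id"])
    cobound_lost = lost & truth.planted_cobound

    peak_frames = [
        cistromes[(f, "control")].peaks[["peak_id", "chrom", "start", "end"]]
        for f in ("A", "B")
    ]
    all_peaks = pd.concat(peak_frames, ignore_index=True)
    called_dep = all_peaks[all_peaks["peak_id"].isin(cobound_lost)]
    links_called = assign_gene_window(
        called_dep, genes, t.window_upstream, t.window_downstream
    )

    # the expression plant uses the truth dependent peaks, as the generator defines
    truth_dep = all_peaks[all_peaks["peak_id"].isin(truth.dependent_peaks)]
    links_truth = assign_gene_window(
        truth_dep, genes, t.window_upstream, t.window_downstream
    )
    cm, truth_e = simulate_expression(cfg, genes, set(links_truth["gene_id"]))
    de_a = de_test(cm, "A", t.de_fold, t.de_p)
    de_b = de_test(cm, "B", t.de_fold, t.de_p)
    coreg = call_coregulation(de_a, de_b)
    flags = build_gene_flags(genes, links_called, coreg.directions)
    result = association_test(flags)
    return {
        "p": result.p,
        "chi2": result.chi2,
        "table": result.table,
        "n_genes": result.n_genes,
        "n_correlated": len(coreg.correlated),
        "n_anti_correlated": len(coreg.anti_correlated),
        "n_planted": len(truth_e.coregulated_genes),
    }


def association_rejection_count(
    cfg: SimConfig, n_seeds: int = 20, alpha: float = 0.01,
    thresholds: Thresholds | None = None,
) -> tuple[int, list[float]]:
    """End-to-end association P across seeds; returns (#P < alpha, P list)."""
    ps = []
    for s in range(n_seeds):
        c = replace(cfg, seed=_sub_seed(cfg.seed, s))
        try:
            ps.append(association_endtoend(c, thresholds)["p"])
        except ValueError:
            # degenerate table (e.g. zero coregulated genes under the null):
            # no evidence of association
            ps.append(1.0)
    return sum(p < alpha for p in ps), ps
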