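"""Scoring of a cross-linked ChIP-MS interactome from peptide intensities.

The stage chain mirrors the standard label-free workflow: peptide intensities
are collapsed to protein iBAQ values (summed intensity over the count of
theoretically observable tryptic peptides), log2-transformed and
median-centered per sample, missing values are imputed from a down-shifted
per-sample Gaussian (width 0.25, downshift 2.0), and bait-vs-control
enrichment is tested with a two-tailed homoscedastic t-test. Interactors are
called at a 10-fold enrichment / P < 0.01 gate, and interactions are
classified as direct vs DNA-bridged by whether the enrichment survives an
8-fold cutoff after promiscuous (Benzonase) nuclease treatment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
# cleave C-terminal to K or R, except before P
_TRYPTIC = re.compile(r"(?<=[KR])(?!P)")

STAGE_RAW = "raw_ibaq"
STAGE_LOG2 = "log2_median"
STAGE_IMPUTED = "imputed"


def digest_protein(sequence: str, min_len: int = 6, max_len: int = 30) -> list[str]:
    """In-silico tryptic digest with zero missed cleavages.

    Cleaves C-terminal to K or R unless the next residue is P; returns
    fragments with ``min_len <= length <= max_len``.
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    bad = set(sequence) - _AA_SET
    if bad:
        raise ValueError(
            f"non-amino-acid character(s) {sorted(bad)} in protein sequence"
        )
    peptides = _TRYPTIC.split(sequence)
    return [p for p in peptides if min_len <= len(p) <= max_len]


def theoretical_peptide_counts(
    proteins: Mapping[str, str], min_len: int = 6, max_len: int = 30
) -> pd.Series:
    """Count of theoretically observable tryptic peptides per protein."""
    return pd.Series(
        {pid: len(digest_protein(seq, min_len, max_len)) for pid, seq in proteins.items()},
        name="n_theoretical",
        dtype=int,
    )


@dataclass
class ProteinQuantMatrix:
    """Proteins x IP-samples quantification matrix.

    ``values`` is a DataFrame (rows: protein ids, columns: sample ids) with
    NaN marking missing cells; ``samples`` carries per-sample annotations
    (columns ``condition`` in {bait, control} and ``nuclease`` in
    {none, mnase, benzonase}, indexed by sample id); ``stage`` tags the
    processing state.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    stage: str = STAGE_RAW

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.samples.index):
            missing = set(self.values.columns) ^ set(self.samples.index)
            raise ValueError(f"sample annotation mismatch for: {sorted(missing)}")
        if self.stage == STAGE_IMPUTED and self.values.isna().any().any():
            raise ValueError("imputed matrix may not contain missing values")
        if self.stage == STAGE_LOG2:
            med = self.values.median(axis=0, skipna=True)
            if not np.allclose(med.to_numpy(dtype=float), 0.0, atol=1e-9):
                raise ValueError("log2_median stage requires per-sample medians of 0")

    def stratum(self, nuclease: str) -> "ProteinQuantMatrix":
        keep = self.samples.index[self.samples["nuclease"] == nuclease]
        if len(keep) == 0:
            raise ValueError(f"no samples with nuclease={nuclease!r}")
        return ProteinQuantMatrix(
            self.values[keep].copy(), self.samples.loc[keep].copy(), self.stage
        )


REQUIRED_PEPTIDE_COLUMNS = (
    "protein_id", "peptide", "sample_id", "condition", "nuclease", "intensity",
)


def compute_ibaq(
    peptides: pd.DataFrame, digest_counts: pd.Series
) -> ProteinQuantMatrix:
    """Collapse a peptide intensity table to protein-level iBAQ values.

    iBAQ(protein, sample) = sum of observed peptide intensities divided by the
    protein's theoretical peptide count. Protein/sample cells with no observed
    peptide are missing (NaN).
    """
    missing_cols = set(REQUIRED_PEPTIDE_COLUMNS) - set(peptides.columns)
    if missing_cols:
        raise ValueError(f"peptide table lacks columns: {sorted(missing_cols)}")
    observed = peptides.dropna(subset=["intensity"])
    if (observed["intensity"] <= 0).any():
        raise ValueError("observed peptide intensities must be > 0")

    prot_ids = peptides["protein_id"].unique()
    unknown = [p for p in prot_ids if p not in digest_counts.index]
    if unknown:
        raise ValueError(f"no theoretical digest for protein(s): {unknown[:5]}")
    zero = digest_counts.loc[prot_ids]
    zero = zero[zero <= 0]
    if len(zero):
        raise ValueError(
            f"zero theoretical peptides (undefined iBAQ denominator) for: "
            f"{list(zero.index[:5])}"
        )

    sums = (
        observed.groupby(["protein_id", "sample_id"], sort=True)["intensity"]
        .sum()
        .unstack("sample_id")
    )
    # carry proteins/samples that appear only as missing observations
    sums = sums.reindex(
        index=pd.Index(sorted(prot_ids)),
        columns=pd.Index(sorted(peptides["sample_id"].unique())),
    )
    ibaq = sums.div(digest_counts.loc[sums.index].astype(float), axis=0)

    ann = (
        peptides[["sample_id", "condition", "nuclease"]]
        .drop_duplicates("sample_id")
        .set_index("sample_id")
        .loc[ibaq.columns]
    )
    return ProteinQuantMatrix(ibaq, ann, STAGE_RAW)


def log2_median_normalize(m: ProteinQuantMatrix) -> ProteinQuantMatrix:
    """log2-transform and center each sample on its observed median."""
    if m.stage != STAGE_RAW:
        raise ValueError(f"expected stage {STAGE_RAW!r}, got {m.stage!r}")
    n_obs = m.values.notna().sum(axis=0)
    empty = n_obs.index[n_obs == 0].tolist()
    if empty:
        raise ValueError(f"sample(s) with zero observed values: {empty}")
    log2 = np.log2(m.values)
    centered = log2 - log2.median(axis=0, skipna=True)
    return ProteinQuantMatrix(centered, m.samples.copy(), STAGE_LOG2)


def impute_missing(
    m: ProteinQuantMatrix,
    width: float = 0.25,
    downshift: float = 2.0,
    seed: int = 0,
    per_sample: bool = True,
) -> ProteinQuantMatrix:
    """Impute missing cells from a down-shifted Gaussian.

    Per sample (default) the observed mean mu and SD sigma are estimated and
    missing cells are drawn i.i.d. from Normal(mu - downshift*sigma,
    (width*sigma)^2) — the left-censored-missingness idiom. ``per_sample=False``
    pools mu/sigma over the whole matrix instead.
    """
    if m.stage != STAGE_LOG2:
        raise ValueError(f"expected stage {STAGE_LOG2!r}, got {m.stage!r}")
    rng = np.random.default_rng(seed)
    vals = m.values.to_numpy(dtype=float).copy()
    mask = np.isnan(vals)
    if per_sample:
        n_obs = (~mask).sum(axis=0)
        thin = m.values.columns[n_obs < 2].tolist()
        if thin:
            raise ValueError(
                f"sample(s) with < 2 observed values (sigma undefined): {thin}"
            )
        mu = np.nanmean(vals, axis=0)
        sigma = np.nanstd(vals, axis=0, ddof=1)
        for j in range(vals.shape[1]):
            miss = mask[:, j]
            if miss.any():
                vals[miss, j] = rng.normal(
                    mu[j] - downshift * sigma[j], width * sigma[j], miss.sum()
                )
    else:
        obs = vals[~mask]
        if obs.size < 2:
            raise ValueError("fewer than 2 observed values in matrix")
        mu, sigma = obs.mean(), obs.std(ddof=1)
        vals[mask] = rng.normal(mu - downshift * sigma, width * sigma, mask.sum())
    out = pd.DataFrame(vals, index=m.values.index, columns=m.values.columns)
    return ProteinQuantMatrix(out, m.samples.copy(), STAGE_IMPUTED)


def detection_flags(m: ProteinQuantMatrix) -> pd.Series:
    """Flag proteins observed in < 50% of samples of BOTH arms (not dropped)."""
    bait = m.samples.index[m.samples["condition"] == "bait"]
    ctl = m.samples.index[m.samples["condition"] == "control"]
    f_bait = m.values[bait].notna().mean(axis=1)
    f_ctl = m.values[ctl].notna().mean(axis=1)
    return ((f_bait < 0.5) & (f_ctl < 0.5)).rename("low_detection")


def test_enrichment(m: ProteinQuantMatrix, nuclease: str | None = None) -> pd.DataFrame:
    """Bait-vs-control differential enrichment per protein.

    log2_enrichment is the mean difference of (imputed) log2 values; the
    P-value comes from a two-tailed pooled-variance (homoscedastic) two-sample
    t-test. Benjamini-Hochberg adjusted P-values are reported alongside.
    """
    if m.stage != STAGE_IMPUTED:
        raise ValueError(f"expected stage {STAGE_IMPUTED!r}, got {m.stage!r}")
    sub = m.stratum(nuclease) if nuclease is not None else m
    bait = sub.samples.index[sub.samples["condition"] == "bait"]
    ctl = sub.samples.index[sub.samples["condition"] == "control"]
    if len(bait) < 2 or len(ctl) < 2:
        raise ValueError(
            f"need >= 2 samples per arm, got bait={len(bait)}, control={len(ctl)}"
        )
    x = sub.values[bait].to_numpy(dtype=float)
    y = sub.values[ctl].to_numpy(dtype=float)
    t, p = stats.ttest_ind(x, y, axis=1, equal_var=True)
    # identical values in both arms: t = 0/0 -> define P = 1 (no evidence)
    p = np.where(np.isnan(p), 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    res = pd.DataFrame(
        {
            "protein_id": sub.values.index,
            "log2_enrichment": x.mean(axis=1) - y.mean(axis=1),
            "t_statistic": t,
            "p_value": p,
        }
    )
    res["adj_p"] = multipletests(res["p_value"].to_numpy(), method="fdr_bh")[1]
    return res


def call_interactors(
    results: pd.DataFrame, fold_cutoff: float = 10.0, p_cutoff: float = 0.01
) -> pd.DataFrame:
    """Apply the fold-change / P-value gate; adds an ``is_interactor`` column."""
    if fold_cutoff <= 0:
        raise ValueError(f"fold_cutoff must be positive, got {fold_cutoff}")
    out = results.copy()
    out["is_interactor"] = (
        out["log2_enrichment"] >= np.log2(fold_cutoff)
    ) & (out["p_value"] < p_cutoff)
    return out


NUCLEASE_DIRECT = "direct"
NUCLEASE_BRIDGED = "dna_bridged"
NUCLEASE_INDETERMINATE = "indeterminate"


def classify_nuclease_sensitivity(
    untreated: pd.DataFrame,
    benzonase: pd.DataFrame,
    mnase: pd.DataFrame | None = None,
    retain_fold: float = 8.0,
    interactor_fold: float = 10.0,
) -> pd.DataFrame:
    """Classify untreated-stratum interactors by Benzonase sensitivity.

    direct: enrichment survives the ``retain_fold`` cutoff after Benzonase;
    dna_bridged: untreated enrichment met the interactor cutoff but Benzonase
    enrichment fell below ``retain_fold``; indeterminate: protein absent from
    the treated stratum. MNase enrichment, if given, is carried through as an
    annotation column (nucleosome-free cleavage does not release direct
    contacts, so classification keys on Benzonase).
    """
    if "is_interactor" not in untreated.columns:
        raise ValueError("untreated results must carry interactor calls")
    calls = untreated[untreated["is_interactor"]].copy()
    benz = benzonase.set_index("protein_id")["log2_enrichment"]
    rows = []
    for _, row in calls.iterrows():
        pid = row["protein_id"]
        if pid not in benz.index or np.isnan(benz.loc[pid]):
            klass = NUCLEASE_INDETERMINATE
            benz_enr = np.nan
        else:
            benz_enr = float(benz.loc[pid])
            if benz_enr >= np.log2(retain_fold):
                klass = NUCLEASE_DIRECT
            elif row["log2_enrichment"] >= np.log2(interactor_fold):
                klass = NUCLEASE_BRIDGED
            else:
                klass = NUCLEASE_INDETERMINATE
        rows.append(
            {
                "protein_id": pid,
                "untreated_log2_enrichment": row["log2_enrichment"],
                "benzonase_log2_enrichment": benz_enr,
                "nuclease_class": klass,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "untreated_log2_enrichment",
            "benzonase_log2_enrichment",
            "nuclease_class",
        ],
    )
    if mnase is not None and len(out):
        mn = mnase.set_index("protein_id")["log2_enrichment"]
        out["mnase_log2_enrichment"] = out["protein_id"].map(mn)
    return out


def score_interactome(
    peptides: pd.DataFrame,
    proteins: Mapping[str, str],
    fold_cutoff: float = 10.0,
    p_cutoff: float = 0.01,
    benzonase_fold: float = 8.0,
    width: float = 0.25,
    downshift: float = 2.0,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Full interactome stage: iBAQ -> normalize -> impute -> test -> classify.

    Each nuclease stratum is scored against its own controls. Returns per-
    stratum enrichment tables, the untreated interactor calls, and the
    nuclease classification of those calls.
    """
    digest = theoretical_peptide_counts(proteins)
    results: dict[str, pd.DataFrame] = {}
    strata = sorted(peptides["nuclease"].unique())
    npep = peptides.groupby("protein_id")["peptide"].nunique()
    for k, stratum in enumerate(strata):
        sub = peptides[peptides["nuclease"] == stratum]
        ibaq = compute_ibaq(sub, digest)
        norm = log2_median_normalize(ibaq)
        imp = impute_missing(norm, width=width, downshift=downshift,
                             seed=(seed * 1009 + k) % (2**31))
        res = test_enrichment(imp)
        res["n_peptides"] = res["protein_id"].map(npep).fillna(0).astype(int)
        res["low_detection"] = res["protein_id"].map(detection_flags(ibaq)).fillna(False)
        results[stratum] = res
    untreated = call_interactors(results["none"], fold_cutoff, p_cutoff)
    results["none"] = untreated
    if "benzonase" in results:
        classes = classify_nuclease_sensitivity(
            untreated,
            results["benzonase"],
            results.get("mnase"),
            retain_fold=benzonase_fold,
            interactor_fold=fold_cutoff,
        )
    else:
        classes = pd.DataFrame(
            columns=[
                "protein_id",
                "untreated_log2_enrichment",
                "benzonase_log2_enrichment",
                "nuclease_class",
            ]
        )
    results["nuclease_classes"] = classes
    return results
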