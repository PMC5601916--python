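"""Peak-to-gene assignment and cross-omic association statistics.

Two windowing conventions link binding sites to genes: nearest gene by
TSS distance within 100 kb, and containment in the strand-aware window from
50 kb upstream of the TSS through 2 kb past the TES. The association between
carrying a knockout-dependent co-bound site and being coregulated is tested
with a Yates-corrected chi-square on the 2x2 gene table. Small-sample helpers
cover the rank-sum comparison of binding strengths and the one-tailed
sequential-ChIP t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GENE_COLUMNS = ("gene_id", "chrom", "start", "end", "strand")


def _check_genes(genes: pd.DataFrame) -> None:
    missing = set(GENE_COLUMNS) - set(genes.columns)
    if missing:
        raise ValueError(f"gene table lacks columns: {sorted(missing)}")
    if not genes["strand"].isin(["+", "-"]).all():
        bad = genes.loc[~genes["strand"].isin(["+", "-"]), "gene_id"]
        raise ValueError(f"genes without strand annotation: {list(bad[:5])}")


def tss(genes: pd.DataFrame) -> np.ndarray:
    """Strand-aware transcription start coordinate (start on +, end on -)."""
    return np.where(genes["strand"] == "+", genes["start"], genes["end"]).astype(int)


def tes(genes: pd.DataFrame) -> np.ndarray:
    return np.where(genes["strand"] == "+", genes["end"], genes["start"]).astype(int)


def _midpoints(peaks: pd.DataFrame) -> np.ndarray:
    return ((peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2).astype(int)


def assign_nearest_gene(
    peaks: pd.DataFrame, genes: pd.DataFrame, max_dist: int = 100_000
) -> pd.DataFrame:
    """Link each peak to the gene with the nearest TSS within ``max_dist``.

    Distance is signed (peak midpoint minus TSS); ties on |distance| break to
    the lexicographically smallest gene_id. Peaks without a gene in range are
    omitted from the result.
    """
    _check_genes(genes)
    g = genes.assign(_tss=tss(genes))
    rows = []
    for chrom, psub in peaks.groupby("chrom", sort=False):
        gsub = g[g["chrom"] == chrom]
        if len(gsub) == 0:
            continue
        mids = _midpoints(psub)
        tss_arr = gsub["_tss"].to_numpy()
        gids = gsub["gene_id"].to_numpy()
        dist = mids[:, None] - tss_arr[None, :]
        absd = np.abs(dist)
        for i, pid in enumerate(psub["peak_id"]):
            dmin = absd[i].min()
            if dmin > max_dist:
                continue
            cand = np.flatnonzero(absd[i] == dmin)
            j = cand[np.argsort(gids[cand], kind="stable")[0]]
            rows.append(
                {
                    "peak_id": pid,
                    "gene_id": gids[j],
                    "convention": "nearest_100kb",
                    "distance": int(dist[i, j]),
                }
            )
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "convention", "distance"])


def assign_gene_window(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    upstream: int = 50_000,
    downstream: int = 2_000,
) -> pd.DataFrame:
    """Link peaks to every gene whose window contains the peak midpoint.

    The window runs from ``upstream`` bp before the TSS through ``downstream``
    bp past the TES, reflected for minus-strand genes; boundaries are closed.
    Multi-gene links are allowed.
    """
    _check_genes(genes)
    g = genes.copy()
    t_start, t_end = tss(g), tes(g)
    lo = np.where(g["strand"] == "+", t_start - upstream, t_end - downstream)
    hi = np.where(g["strand"] == "+", t_end + downstream, t_start + upstream)
    g = g.assign(_lo=lo, _hi=hi, _tss=t_start)
    rows = []
    for chrom, psub in peaks.groupby("chrom", sort=False):
        gsub = g[g["chrom"] == chrom]
        if len(gsub) == 0:
            continue
        mids = _midpoints(psub)
        inside = (mids[:, None] >= gsub["_lo"].to_numpy()[None, :]) & (
            mids[:, None] <= gsub["_hi"].to_numpy()[None, :]
        )
        pi, gi = np.nonzero(inside)
        for a, b in zip(pi, gi):
            rows.append(
                {
                    "peak_id": psub["peak_id"].iat[a],
                    "gene_id": gsub["gene_id"].iat[b],
                    "convention": "tss50k_tes2k",
                    "distance": int(mids[a] - gsub["_tss"].iat[b]),
                }
            )
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "convention", "distance"])


def chi2_test(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, optionally Yates-corrected."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table < 0).any():
        raise ValueError("table counts must be non-negative")
    stat, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(stat), float(p)


@dataclass
class AssociationResult:
    table: np.ndarray
    chi2: float
    p: float
    n_genes: int


def association_test(gene_flags: pd.DataFrame) -> AssociationResult:
    """Yates chi-square of dependent-site linkage x coregulation over genes.

    ``gene_flags`` needs boolean columns ``has_dependent_link`` and
    ``coregulated``; rows are the gene universe (coregulated + unchanged).
    Degenerate margins (every gene in one class) raise.
    """
    for col in ("has_dependent_link", "coregulated"):
        if col not in gene_flags.columns:
            raise ValueError(f"gene_flags lacks column {col!r}")
    link = gene_flags["has_dependent_link"].astype(bool).to_numpy()
    coreg = gene_flags["coregulated"].astype(bool).to_numpy()
    table = np.array(
        [
            [int((link & coreg).sum()), int((link & ~coreg).sum())],
            [int((~link & coreg).sum()), int((~link & ~coreg).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate margin: all genes fall in one class")
    stat, p = chi2_test(table, yates=True)
    return AssociationResult(table=table, chi2=stat, p=p, n_genes=len(gene_flags))


def binding_strength_test(
    lost_values, unchanged_values, exact_max_n: int = 20
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing signal between two peak groups.

    Exact P for combined n <= ``exact_max_n`` (and no ties); normal
    approximation with tie correction otherwise. Completely tied data give
    P = 1.
    """
    x = np.asarray(lost_values, dtype=float)
    y = np.asarray(unchanged_values, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need >= 3 values per group")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def rechip_test(signal_replicates, control_replicates) -> tuple[float, float]:
    """One-tailed (greater) pooled-variance t-test for sequential ChIP signal."""
    x = np.asarray(signal_replicates, dtype=float)
    y = np.asarray(control_replicates, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 replicates per group")
    t, p = stats.ttest_ind(x, y, equal_var=True, alternative="greater")
    if np.isnan(p):
        t, p = 0.0, 0.5
    return float(t), float(p)


def build_gene_flags(
    genes: pd.DataFrame,
    dependent_links: pd.DataFrame,
    coregulation_classes: pd.DataFrame,
    include_anti_correlated: bool = False,
) -> pd.DataFrame:
    """Assemble the association-test gene universe.

    The universe is coregulated genes plus unchanged genes (genes failing the
    differential gate in BOTH perturbations); genes changed in exactly one
    perturbation are ambiguous and excluded. ``coregulation_classes`` is the
    per-gene table from coregulation calling (gene_id, passes_A, passes_B,
    class). Anti-correlated genes count as coregulated only when
    ``include_anti_correlated`` is set.
    """
    cls = coregulation_classes.set_index("gene_id")
    coreg_classes = {"correlated"}
    if include_anti_correlated:
        coreg_classes.add("anti_correlated")
    is_coreg = cls["class"].isin(coreg_classes)
    unchanged = ~cls["passes_A"] & ~cls["passes_B"]
    universe = cls.index[is_coreg | unchanged]
    linked = set(dependent_links["gene_id"])
    out = pd.DataFrame(
        {
            "gene_id": universe,
            "coregulated": is_coreg.loc[universe].to_numpy(),
            "has_dependent_link": [g in linked for g in universe],
        }
    )
    return out.reset_index(drop=True)
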