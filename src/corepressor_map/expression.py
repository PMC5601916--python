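"""Differential expression across two perturbations and coregulation calling.

The differential engine is deliberately simple and swappable: log2 counts per
million (pseudocount 1) followed by a per-gene Welch t-test. What matters
downstream is the published gate — |fold change| >= 1.7 with P < 0.05 — and
the coregulation logic: genes passing the gate in both perturbations are split
by direction agreement into correlated and anti-correlated sets, and the
overlap of the two pass lists is scored with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CONDITIONS = ("control_A", "KO_A", "control_B", "KD_B")
ARMS = {"A": ("control_A", "KO_A"), "B": ("control_B", "KD_B")}


@dataclass
class CountMatrix:
    """Gene x sample counts with condition labels.

    ``counts``: DataFrame indexed by gene_id, columns are sample ids.
    ``samples``: DataFrame indexed by sample id with a ``condition`` column.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.samples.index):
            raise ValueError("counts columns must match sample annotation index")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        sizes = self.samples["condition"].value_counts()
        thin = sizes[sizes < 2]
        if len(thin):
            raise ValueError(
                f"every condition needs >= 2 samples; short: {dict(thin)}"
            )

    def arm(self, perturbation: str) -> tuple[pd.Index, pd.Index]:
        ctl_name, trt_name = ARMS[perturbation]
        ctl = self.samples.index[self.samples["condition"] == ctl_name]
        trt = self.samples.index[self.samples["condition"] == trt_name]
        return ctl, trt


def normalize_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(counts-per-million + 1); library size is the column sum."""
    lib = counts.sum(axis=0).astype(float)
    empty = lib.index[lib <= 0].tolist()
    if empty:
        raise ValueError(f"empty sample(s): {empty}")
    return np.log2(counts.div(lib, axis=1) * 1e6 + 1.0)


def apply_de_gate(log2_fold_change, p_value, fold: float = 1.7,
                  p_cutoff: float = 0.05):
    """The differential gate: |fold change| >= fold (inclusive) AND P < p_cutoff."""
    if fold <= 0:
        raise ValueError("fold must be positive")
    return (np.abs(np.asarray(log2_fold_change)) >= np.log2(fold)) & (
        np.asarray(p_value) < p_cutoff
    )


def de_test(
    cm: CountMatrix,
    perturbation: str,
    fold: float = 1.7,
    p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Welch t-test on log2-CPM per gene; gate at (fold, p_cutoff).

    Genes with zero variance and equal means in both arms get P = 1.
    """
    if perturbation not in ARMS:
        raise ValueError(f"perturbation must be one of {sorted(ARMS)}")
    ctl, trt = cm.arm(perturbation)
    if len(ctl) < 2 or len(trt) < 2:
        raise ValueError("need >= 2 samples per arm")
    logcpm = normalize_cpm(cm.counts)
    x = logcpm[trt].to_numpy()
    y = logcpm[ctl].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
    lfc = x.mean(axis=1) - y.mean(axis=1)
    # degenerate genes: zero variance in both arms
    degenerate = np.isnan(p)
    p = np.where(degenerate & (lfc == 0), 1.0, p)
    p = np.where(degenerate & (lfc != 0), 0.0, p)
    res = pd.DataFrame(
        {
            "gene_id": cm.counts.index,
            "log2_fold_change": lfc,
            "p_value": p,
        }
    )
    res["passes"] = apply_de_gate(
        res["log2_fold_change"].to_numpy(), res["p_value"].to_numpy(), fold, p_cutoff
    )
    res["direction"] = np.sign(res["log2_fold_change"]).astype(int)
    return res


@dataclass
class CoregulationSet:
    correlated: list = field(default_factory=list)
    anti_correlated: list = field(default_factory=list)
    directions: pd.DataFrame | None = None
    overlap_table: np.ndarray | None = None
    overlap_odds: float = float("nan")
    overlap_p: float = float("nan")


def call_coregulation(de_a: pd.DataFrame, de_b: pd.DataFrame) -> CoregulationSet:
    """Split genes passing the gate in both perturbations by sign agreement.

    Overlap significance of the two pass lists is a Fisher exact test on the
    pass/fail x perturbation 2x2 table.
    """
    if set(de_a["gene_id"]) != set(de_b["gene_id"]):
        raise ValueError("differential results cover different gene universes")
    a = de_a.set_index("gene_id")
    b = de_b.set_index("gene_id").loc[a.index]
    both = a["passes"] & b["passes"]
    same_dir = a["direction"] == b["direction"]
    correlated = sorted(a.index[both & same_dir])
    anti = sorted(a.index[both & ~same_dir])
    table = np.array(
        [
            [int((a["passes"] & b["passes"]).sum()),
             int((a["passes"] & ~b["passes"]).sum())],
            [int((~a["passes"] & b["passes"]).sum()),
             int((~a["passes"] & ~b["passes"]).sum())],
        ]
    )
    odds, p = stats.fisher_exact(table)
    directions = pd.DataFrame(
        {
            "gene_id": a.index,
            "dir_A": a["direction"].to_numpy(),
            "dir_B": b["direction"].to_numpy(),
            "passes_A": a["passes"].to_numpy(),
            "passes_B": b["passes"].to_numpy(),
        }
    ).reset_index(drop=True)
    directions["class"] = "none"
    directions.loc[directions["gene_id"].isin(correlated), "class"] = "correlated"
    directions.loc[directions["gene_id"].isin(anti), "class"] = "anti_correlated"
    return CoregulationSet(
        correlated=correlated,
        anti_correlated=anti,
        directions=directions,
        overlap_table=table,
        overlap_odds=float(odds),
        overlap_p=float(p),
    )
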