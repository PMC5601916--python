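"""Peak-set quantification and algebra for transcription-factor cistromes.

Coordinates are 0-based half-open throughout. Peak signal is reads-per-million
(rpm = reads x 1e6 / library size); browser-track scale RPTM is 10x rpm.
Co-binding uses the reciprocal-overlap rule: a peak is co-bound when a partner
peak overlaps it by at least half of either peak's length and the partner
factor shows at least 1 rpm there. Knockout dependency is a pseudocounted
fold-decrease of rpm over matched peak intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

PEAK_COLUMNS = ("peak_id", "chrom", "start", "end", "reads", "input_reads")


def compute_rpm(reads, library_size):
    """Reads per million mapped reads. RPTM (track scale) is 10x this."""
    lib = np.asarray(library_size, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library_size must be > 0")
    return np.asarray(reads, dtype=float) * 1e6 / lib


def rptm(reads, library_size):
    return 10.0 * compute_rpm(reads, library_size)


@dataclass
class Cistrome:
    """A named peak set of one factor in one condition.

    ``peaks`` columns: peak_id, chrom, start, end, reads, input_reads (plus
    derived rpm / input_rpm). ``input_library_size`` defaults to
    ``library_size``.
    """

    factor: str
    condition: str
    peaks: pd.DataFrame
    library_size: int
    input_library_size: int | None = None

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        missing = set(PEAK_COLUMNS) - set(self.peaks.columns)
        if missing:
            raise ValueError(f"peak table lacks columns: {sorted(missing)}")
        if self.peaks["peak_id"].duplicated().any():
            dupes = self.peaks.loc[self.peaks["peak_id"].duplicated(), "peak_id"]
            raise ValueError(f"duplicate peak ids: {list(dupes[:5])}")
        if ((self.peaks["reads"] < 0) | (self.peaks["input_reads"] < 0)).any():
            raise ValueError("read counts must be non-negative")
        bad = self.peaks["start"] >= self.peaks["end"]
        if bad.any():
            raise ValueError(
                f"invalid intervals (start >= end) for: "
                f"{list(self.peaks.loc[bad, 'peak_id'][:5])}"
            )
        if self.input_library_size is None:
            self.input_library_size = self.library_size
        self.peaks = self.peaks.copy()
        self.peaks["rpm"] = compute_rpm(self.peaks["reads"], self.library_size)
        self.peaks["input_rpm"] = compute_rpm(
            self.peaks["input_reads"], self.input_library_size
        )

    def __len__(self) -> int:
        return len(self.peaks)


def filter_peaks(
    c: Cistrome,
    min_rpm: float,
    input_fold: float = 3.0,
    input_pseudocount: float = 0.1,
) -> Cistrome:
    """Keep peaks with rpm > min_rpm that exceed input_fold x (input rpm + pc)."""
    if min_rpm < 0 or input_fold < 0:
        raise ValueError("thresholds must be non-negative")
    p = c.peaks
    keep = (p["rpm"] > min_rpm) & (
        p["rpm"] > input_fold * (p["input_rpm"] + input_pseudocount)
    )
    return Cistrome(
        c.factor,
        c.condition,
        p.loc[keep, list(PEAK_COLUMNS)].reset_index(drop=True),
        c.library_size,
        c.input_library_size,
    )


@dataclass
class OverlapPartition:
    """Partition of two filtered cistromes into co-bound and single-factor peaks.

    ``pairs`` holds one row per co-bound A-peak with its maximally overlapping
    qualifying B partner (and symmetrically a ``b_pairs`` view); ``co_a``/
    ``co_b`` are the co-bound peak-id sets, ``a_only``/``b_only`` the rest.
    """

    pairs: pd.DataFrame
    co_a: list = field(default_factory=list)
    co_b: list = field(default_factory=list)
    a_only: list = field(default_factory=list)
    b_only: list = field(default_factory=list)


def _build_trees(peaks: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in peaks.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), i)
            for s, e, i in zip(sub["start"], sub["end"], sub.index)
        )
    return trees


def _cobound_pairs(pa, pb, min_frac, min_other_rpm):
    """Qualifying pair test: overlap >= min_frac of either peak's length AND
    the partner factor's rpm >= min_other_rpm (evaluated from both sides)."""
    trees = _build_trees(pb)
    hits = {}
    for i, (chrom, s, e, rpm_a) in enumerate(
        zip(pa["chrom"], pa["start"], pa["end"], pa["rpm"])
    ):
        tree = trees.get(chrom)
        if tree is None:
            continue
        best = None
        for iv in tree.overlap(int(s), int(e)):
            j = iv.data
            ovl = min(e, iv.end) - max(s, iv.begin)
            if ovl <= 0:
                continue
            from_a = ovl >= min_frac * (e - s) and pb["rpm"].iat[j] >= min_other_rpm
            from_b = ovl >= min_frac * (iv.end - iv.begin) and rpm_a >= min_other_rpm
            if not (from_a or from_b):
                continue
            key = (ovl, pb["peak_id"].iat[j])
            # maximal overlap wins; ties -> lexicographically smaller partner id
            if best is None or key[0] > best[0] or (key[0] == best[0] and key[1] < best[1]):
                best = (ovl, pb["peak_id"].iat[j], j)
        if best is not None:
            hits[i] = best
    return hits


def overlap_cistromes(
    a: Cistrome,
    b: Cistrome,
    min_frac: float = 0.5,
    min_other_rpm: float = 1.0,
) -> OverlapPartition:
    """Partition two cistromes into co-bound / a_only / b_only peaks."""
    only_a = set(a.peaks["chrom"]) - set(b.peaks["chrom"])
    only_b = set(b.peaks["chrom"]) - set(a.peaks["chrom"])
    if only_a or only_b:
        raise ValueError(
            f"chromosome names present in only one cistrome: "
            f"{sorted(only_a | only_b)}"
        )
    pa = a.peaks.reset_index(drop=True)
    pb = b.peaks.reset_index(drop=True)
    hits_a = _cobound_pairs(pa, pb, min_frac, min_other_rpm)
    hits_b = _cobound_pairs(pb, pa, min_frac, min_other_rpm)

    rows = []
    for i, (ovl, b_id, j) in sorted(hits_a.items()):
        rows.append(
            {
                "a_peak_id": pa["peak_id"].iat[i],
                "b_peak_id": b_id,
                "overlap_bp": int(ovl),
                "overlap_frac_a": ovl / (pa["end"].iat[i] - pa["start"].iat[i]),
                "overlap_frac_b": ovl / (pb["end"].iat[j] - pb["start"].iat[j]),
            }
        )
    pairs = pd.DataFrame(
        rows,
        columns=["a_peak_id", "b_peak_id", "overlap_bp",
                 "overlap_frac_a", "overlap_frac_b"],
    )
    co_a = sorted(pa["peak_id"].iloc[list(hits_a)]) if hits_a else []
    co_b = sorted(pb["peak_id"].iloc[list(hits_b)]) if hits_b else []
    a_only = sorted(set(pa["peak_id"]) - set(co_a))
    b_only = sorted(set(pb["peak_id"]) - set(co_b))
    return OverlapPartition(pairs, co_a, co_b, a_only, b_only)


def venn_counts(partition: OverlapPartition) -> dict[str, int]:
    """Venn counts; the co-bound cell counts co-bound A-side peaks once each."""
    return {
        "co_bound": len(partition.co_a),
        "a_only": len(partition.a_only),
        "b_only": len(partition.b_only),
    }


def _frac_overlapped(query: pd.DataFrame, c: Cistrome, min_frac: float):
    """Fraction of query peaks overlapped by C by >= min_frac of query length."""
    trees = _build_trees(c.peaks)
    hit_ids = []
    for pid, chrom, s, e in zip(
        query["peak_id"], query["chrom"], query["start"], query["end"]
    ):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.overlap(int(s), int(e)):
            ovl = min(e, iv.end) - max(s, iv.begin)
            if ovl >= min_frac * (e - s):
                hit_ids.append(pid)
                break
    frac = len(hit_ids) / len(query) if len(query) else float("nan")
    return frac, hit_ids


def triple_intersection(
    partition: OverlapPartition,
    a: Cistrome,
    b: Cistrome,
    c: Cistrome,
    min_frac: float = 0.5,
) -> dict:
    """Overlap of a third factor C with each peak class of an A/B partition.

    Returns the C-bound fraction of co-bound (A-side intervals), a_only and
    b_only peaks, the triple-bound peak ids, and Pearson chi-square tests of
    co-bound vs each single-factor class.
    """
    from .integration import chi2_test

    if not partition.co_a:
        raise ValueError("empty co-bound set")
    pa = a.peaks.set_index("peak_id", drop=False)
    pb = b.peaks.set_index("peak_id", drop=False)
    classes = {
        "co_bound": pa.loc[partition.co_a],
        "a_only": pa.loc[partition.a_only],
        "b_only": pb.loc[partition.b_only],
    }
    out: dict = {"fractions": {}, "counts": {}, "triple_bound": []}
    for name, sub in classes.items():
        if len(sub) == 0:
            out["fractions"][name] = float("nan")
            out["counts"][name] = {"n": 0, "hits": 0}
            continue
        frac, hit_ids = _frac_overlapped(sub, c, min_frac)
        out["fractions"][name] = frac
        out["counts"][name] = {"n": int(len(sub)), "hits": int(len(hit_ids))}
        if name == "co_bound":
            out["triple_bound"] = hit_ids
    out["tests"] = {}
    co = out["counts"]["co_bound"]
    for other in ("a_only", "b_only"):
        oc = out["counts"][other]
        if oc["n"] == 0:
            continue
        table = np.array(
            [[co["hits"], co["n"] - co["hits"]], [oc["hits"], oc["n"] - oc["hits"]]]
        )
        if (table.sum(axis=0) == 0).any():
            # identical saturated/empty classes: no comparison possible
            out["tests"][f"co_bound_vs_{other}"] = {"chi2": None, "p": None}
            continue
        stat, p = chi2_test(table, yates=False)
        out["tests"][f"co_bound_vs_{other}"] = {"chi2": stat, "p": p}
    return out


def classify_dependency(
    ctl: Cistrome, ko: Cistrome, fold: float = 2.0, pseudocount: float = 0.1
) -> pd.DataFrame:
    """Call peaks lost upon knockout by pseudocounted rpm fold-decrease.

    Peaks must match by peak_id across the two conditions; fold_decrease =
    (ctl_rpm + pc) / (ko_rpm + pc); status is 'lost' iff fold_decrease >= fold.
    """
    c = ctl.peaks.set_index("peak_id")
    k = ko.peaks.set_index("peak_id")
    mismatch = set(c.index) ^ set(k.index)
    if mismatch:
        raise ValueError(
            f"peak ids present in only one condition: {sorted(mismatch)[:5]}"
        )
    k = k.loc[c.index]
    with np.errstate(divide="ignore", invalid="ignore"):
        fold_dec = (c["rpm"] + pseudocount) / (k["rpm"] + pseudocount)
    return pd.DataFrame(
        {
            "peak_id": c.index,
            "control_rpm": c["rpm"].to_numpy(),
            "ko_rpm": k["rpm"].to_numpy(),
            "fold_decrease": fold_dec.to_numpy(),
            "status": np.where(fold_dec.to_numpy() >= fold, "lost", "unchanged"),
        }
    ).reset_index(drop=True)


def filter_on_knockout(
    ctl: Cistrome, ko: Cistrome, persist_frac: float = 0.5
) -> Cistrome:
    """Drop control peaks whose knockout rpm stays >= persist_frac of control.

    Peaks that persist after deleting the factor are treated as nonspecific.
    """
    calls = classify_dependency(ctl, ko, fold=1.0, pseudocount=0.0)
    keep_ids = set(
        calls.loc[calls["ko_rpm"] < persist_frac * calls["control_rpm"], "peak_id"]
    )
    kept = ctl.peaks[ctl.peaks["peak_id"].isin(keep_ids)]
    return Cistrome(
        ctl.factor,
        ctl.condition,
        kept[list(PEAK_COLUMNS)].reset_index(drop=True),
        ctl.library_size,
        ctl.input_library_size,
    )


def _union_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    both = pd.concat(
        [a[["chrom", "start", "end"]], b[["chrom", "start", "end"]]]
    ).sort_values(["chrom", "start", "end"])
    rows = []
    for chrom, sub in both.groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _signal_over(union: pd.DataFrame, c: Cistrome) -> np.ndarray:
    """rpm of cistrome c attributed to each union interval, apportioning each
    peak's rpm by the fraction of the peak inside the interval."""
    trees = _build_trees(c.peaks.reset_index(drop=True))
    peaks = c.peaks.reset_index(drop=True)
    sig = np.zeros(len(union))
    for i, (chrom, s, e) in enumerate(
        zip(union["chrom"], union["start"], union["end"])
    ):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.overlap(int(s), int(e)):
            j = iv.data
            ovl = min(e, iv.end) - max(s, iv.begin)
            sig[i] += peaks["rpm"].iat[j] * ovl / (iv.end - iv.begin)
    return sig


def correlate_cistromes(a: Cistrome, b: Cistrome) -> float:
    """Pearson r of the two factors' rpm over the union peak set."""
    union = _union_intervals(a.peaks, b.peaks)
    if len(union) < 3:
        raise ValueError(f"need >= 3 union peaks, got {len(union)}")
    x = _signal_over(union, a)
    y = _signal_over(union, b)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance signal vector")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, _ = stats.pearsonr(x, y)
    return float(r)
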