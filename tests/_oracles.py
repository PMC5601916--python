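"""Independent brute-force oracles for the test suite.

Everything here is written from the textbook definition with plain Python
loops (or closed forms), deliberately sharing no code path with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


# ------------------------------------------------------------ quantification

def ibaq_oracle(rows, digest_counts):
    """rows: iterable of (protein_id, sample_id, intensity_or_None).

    Returns {(protein, sample): ibaq} for cells with >= 1 observed peptide.
    """
    sums: dict = {}
    for pid, sid, val in rows:
        if val is None or (isinstance(val, float) and math.isnan(val)):
            continue
        sums[(pid, sid)] = sums.get((pid, sid), 0.0) + val
    return {k: v / digest_counts[k[0]] for k, v in sums.items()}


def median_norm_oracle(columns):
    """columns: {sample: [values or None]}; returns same shape, log2-centered."""
    out = {}
    for sample, vals in columns.items():
        obs = sorted(math.log2(v) for v in vals if v is not None)
        n = len(obs)
        med = (obs[n // 2] if n % 2 else 0.5 * (obs[n // 2 - 1] + obs[n // 2]))
        out[sample] = [
            None if v is None else math.log2(v) - med for v in vals
        ]
    return out


# ------------------------------------------------------------------- t-tests

def pooled_t_oracle(x, y):
    """Two-tailed homoscedastic two-sample t-test from the pooled-variance
    formula and the t CDF."""
    x, y = list(map(float, x)), list(map(float, y))
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    ssx = sum((v - mx) ** 2 for v in x)
    ssy = sum((v - my) ** 2 for v in y)
    df = nx + ny - 2
    sp2 = (ssx + ssy) / df
    se = math.sqrt(sp2 * (1 / nx + 1 / ny))
    if se == 0:
        return 0.0, 1.0
    t = (mx - my) / se
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def welch_t_oracle(x, y):
    x, y = list(map(float, x)), list(map(float, y))
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        return 0.0, 1.0
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def one_tailed_pooled_t_oracle(x, y):
    t, p_two = pooled_t_oracle(x, y)
    return t, stats.t.sf(t, len(x) + len(y) - 2)


# ---------------------------------------------------------------- chi-square

def chi2_oracle(table, yates=False):
    """Pearson chi-square on a 2x2 table by Sum (|O-E|-c)^2 / E."""
    table = [[float(v) for v in row] for row in table]
    n = sum(sum(row) for row in table)
    rows = [sum(r) for r in table]
    cols = [table[0][j] + table[1][j] for j in range(2)]
    stat = 0.0
    c = 0.5 if yates else 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            stat += max(abs(table[i][j] - e) - c, 0.0) ** 2 / e
    return stat, stats.chi2.sf(stat, 1)


# ------------------------------------------------------------- Mann-Whitney

def mannwhitney_exact_oracle(x, y):
    """Exact two-sided Mann-Whitney by full enumeration of group assignments.

    P = fraction of assignments whose U is at least as far from n*m/2 as the
    observed U.
    """
    x, y = list(map(float, x)), list(map(float, y))
    pooled = x + y
    n, m = len(x), len(y)

    def u_of(group_x):
        u = 0
        group_y = list(pooled)
        for v in group_x:
            group_y.remove(v)
        for a in group_x:
            for b in group_y:
                if a > b:
                    u += 1
                elif a == b:
                    u += 0.5
        return u

    u_obs = u_of(x)
    center = n * m / 2
    count = total = 0
    for combo in itertools.combinations(range(n + m), n):
        u = u_of([pooled[i] for i in combo])
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return u_obs, count / total


# ------------------------------------------------------------------ Pearson r

def pearson_r_oracle(x, y):
    x, y = list(map(float, x)), list(map(float, y))
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)


# ----------------------------------------------------------------- intervals

def overlap_partition_oracle(peaks_a, peaks_b, min_frac=0.5, min_other_rpm=1.0):
    """All-pairs reciprocal-overlap partition.

    peaks: list of dicts with peak_id, chrom, start, end, rpm. A pair
    qualifies if it overlaps >= min_frac of either peak's length and the
    partner's rpm >= min_other_rpm from that side. Returns (co_a, co_b) sets.
    """
    co_a, co_b = set(), set()
    for pa in peaks_a:
        for pb in peaks_b:
            if pa["chrom"] != pb["chrom"]:
                continue
            ovl = min(pa["end"], pb["end"]) - max(pa["start"], pb["start"])
            if ovl <= 0:
                continue
            from_a = (
                ovl >= min_frac * (pa["end"] - pa["start"])
                and pb["rpm"] >= min_other_rpm
            )
            from_b = (
                ovl >= min_frac * (pb["end"] - pb["start"])
                and pa["rpm"] >= min_other_rpm
            )
            if from_a or from_b:
                co_a.add(pa["peak_id"])
                co_b.add(pb["peak_id"])
    return co_a, co_b


def filter_oracle(peaks, min_rpm, input_fold=3.0, pc=0.1):
    return {
        p["peak_id"]
        for p in peaks
        if p["rpm"] > min_rpm and p["rpm"] > input_fold * (p["input_rpm"] + pc)
    }


def nearest_gene_oracle(peaks, genes, max_dist=100_000):
    """peaks: dicts (peak_id, chrom, start, end); genes: dicts with
    gene_id, chrom, start, end, strand. Returns {peak_id: (gene_id, dist)}."""
    out = {}
    for p in peaks:
        mid = (p["start"] + p["end"]) // 2
        best = None
        for g in genes:
            if g["chrom"] != p["chrom"]:
                continue
            tss = g["start"] if g["strand"] == "+" else g["end"]
            d = mid - tss
            key = (abs(d), g["gene_id"])
            if best is None or key < best[:2]:
                best = (abs(d), g["gene_id"], d)
        if best is not None and best[0] <= max_dist:
            out[p["peak_id"]] = (best[1], best[2])
    return out


def window_link_oracle(peaks, genes, upstream=50_000, downstream=2_000):
    out = set()
    for p in peaks:
        mid = (p["start"] + p["end"]) // 2
        for g in genes:
            if g["chrom"] != p["chrom"]:
                continue
            if g["strand"] == "+":
                lo, hi = g["start"] - upstream, g["end"] + downstream
            else:
                lo, hi = g["start"] - downstream, g["end"] + upstream
            if lo <= mid <= hi:
                out.add((p["peak_id"], g["gene_id"]))
    return out


def scan_oracle(seq, matrix, background):
    """Best PWM log2-odds over all offsets and both strands, by plain loops."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[b] for b in reversed(seq))
    L = len(matrix)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    best = -math.inf
    for s in (seq, rc):
        for off in range(len(s) - L + 1):
            score = 0.0
            for j in range(L):
                base = s[off + j]
                if base == "N":
                    score = -math.inf
                    break
                p = max(matrix[j][idx[base]], 1e-9)
                score += math.log2(p / background[idx[base]])
            best = max(best, score)
    return best
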