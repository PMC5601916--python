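"""PWM scanning of peak windows and chi-square comparison of motif frequency.

Windows of 200 bp centered on peak midpoints are scanned on both strands with
log-odds (bits) position weight matrices; a window is a hit when its best
score reaches the PWM threshold (default: 80% of the maximal attainable
log-odds). Motif frequencies of two peak classes are compared with Pearson's
chi-square on the 2x2 hit table, falling back to Fisher's exact test when an
expected cell drops below 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_CODE["N"] = 4
_PROB_FLOOR = 1e-9


@dataclass
class PWM:
    """Position probability matrix with a background model.

    ``matrix`` is L x 4 (A, C, G, T probabilities per position); scores are
    log2 odds against ``background``. ``threshold`` is in bits; when None it
    defaults to ``threshold_frac`` of the maximal attainable score.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    threshold: float | None = None
    threshold_frac: float = 0.8

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM must have length >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")
        if self.threshold is None:
            self.threshold = self.threshold_frac * self.max_score()

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        p = np.clip(self.matrix, _PROB_FLOOR, None)
        return np.log2(p / self.background)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass
class MotifHit:
    peak_id: object
    pwm_name: str
    score: float
    position: int
    strand: str


_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    try:
        return np.fromiter((_CODE[b] for b in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from exc


def _offset_scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Best-per-offset log-odds scores of a coded forward-strand sequence.

    A fifth column of -inf handles N: any window containing N scores -inf.
    """
    L = lom.shape[0]
    n_off = len(codes) - L + 1
    padded = np.hstack([lom, np.full((L, 1), -np.inf)])
    scores = np.zeros(n_off)
    for j in range(L):
        scores += padded[j, codes[j : j + n_off]]
    return scores


def scan_window(sequence: str, pwm: PWM, peak_id=None) -> MotifHit | None:
    """Best log-odds hit of a PWM in a window, both strands, or None.

    The reverse strand is scanned via the reverse complement; positions are
    offsets on the given (forward) sequence of the match start.
    """
    L = len(pwm)
    if len(sequence) < L:
        raise ValueError(
            f"window of length {len(sequence)} shorter than PWM length {L}"
        )
    lom = pwm.log_odds()
    fwd = _offset_scores(encode(sequence), lom)
    rev = _offset_scores(encode(reverse_complement(sequence)), lom)
    best_f, best_r = fwd.max(), rev.max()
    if best_r > best_f:
        score, strand = best_r, "-"
        # position of the match start on the forward sequence
        pos = len(sequence) - L - int(rev.argmax())
    else:
        score, strand = best_f, "+"
        pos = int(fwd.argmax())
    if not np.isfinite(score) or score < pwm.threshold:
        return None
    return MotifHit(peak_id, pwm.name, float(score), pos, strand)


def peak_windows(
    peaks: pd.DataFrame, genome: dict[str, str], window: int = 200
) -> list[tuple[object, str]]:
    """Extract window-sized sequences centered on peak midpoints.

    Windows running past chromosome bounds are clipped with a warning.
    """
    out = []
    clipped = 0
    for pid, chrom, s, e in zip(
        peaks["peak_id"], peaks["chrom"], peaks["start"], peaks["end"]
    ):
        if chrom not in genome:
            raise ValueError(f"chromosome {chrom!r} absent from genome")
        seq = genome[chrom]
        mid = (int(s) + int(e)) // 2
        lo, hi = mid - window // 2, mid + window - window // 2
        if lo < 0 or hi > len(seq):
            clipped += 1
            lo, hi = max(lo, 0), min(hi, len(seq))
        out.append((pid, seq[lo:hi]))
    if clipped:
        warnings.warn(f"{clipped} window(s) clipped at chromosome bounds")
    return out


def motif_frequency(
    peaks: pd.DataFrame, genome: dict[str, str], pwm: PWM, window: int = 200
) -> dict:
    """Fraction of a peak class whose window contains a PWM hit."""
    if len(peaks) == 0:
        raise ValueError("empty peak class")
    hits = []
    for pid, seq in peak_windows(peaks, genome, window):
        hit = scan_window(seq, pwm, peak_id=pid)
        if hit is not None:
            hits.append(hit)
    return {
        "pwm": pwm.name,
        "n": int(len(peaks)),
        "hits": len(hits),
        "fraction": len(hits) / len(peaks),
        "hit_records": hits,
    }


def compare_motif_enrichment(
    peaks_a: pd.DataFrame,
    peaks_b: pd.DataFrame,
    genome: dict[str, str],
    pwm: PWM,
    window: int = 200,
    labels: tuple[str, str] = ("classA", "classB"),
) -> dict:
    """2x2 Pearson chi-square of motif frequency between two peak classes.

    Uses no continuity correction; if any expected cell is < 1 the comparison
    switches to Fisher's exact test with a warning.
    """
    fa = motif_frequency(peaks_a, genome, pwm, window)
    fb = motif_frequency(peaks_b, genome, pwm, window)
    table = np.array(
        [[fa["hits"], fa["n"] - fa["hits"]], [fb["hits"], fb["n"] - fb["hits"]]]
    )
    expected = stats.contingency.expected_freq(table)
    if (expected < 1).any():
        warnings.warn(
            f"expected cell < 1 for {pwm.name}; using Fisher's exact test"
        )
        _, p = stats.fisher_exact(table)
        chi2 = float("nan")
        method = "fisher"
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        chi2 = float(chi2)
        method = "pearson_chi2"
    return {
        "pwm": pwm.name,
        labels[0]: fa,
        labels[1]: fb,
        "table": table,
        "chi2": chi2,
        "p": float(p),
        "method": method,
    }


def _consensus_pwm(name: str, consensus: str, p: float = 0.85) -> PWM:
    """PWM concentrating probability ``p`` on the consensus base; 'N' positions
    are uniform."""
    rows = []
    off = (1.0 - p) / 3.0
    for b in consensus:
        if b == "N":
            rows.append([0.25] * 4)
        else:
            row = [off] * 4
            row[_CODE[b]] = p
            rows.append(row)
    return PWM(name, np.array(rows))


def builtin_pwms() -> dict[str, PWM]:
    """Toy motif models for the synthetic genome.

    hnf4_dr1: a direct repeat of AGGTCA-like half sites with 1 bp spacer
    (nuclear-receptor DR1, HNF4a-like); reverb_dr2: the same half sites with a
    2 bp spacer (Rev-erb-like DR2); cebp: a C/EBP-like palindrome.
    """
    return {
        "hnf4_dr1": _consensus_pwm("hnf4_dr1", "AGGTCAAAGGTCA"),
        "reverb_dr2": _consensus_pwm("reverb_dr2", "AGGTCANNAGGTCA"),
        "cebp": _consensus_pwm("cebp", "TTGCGCAA"),
    }
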