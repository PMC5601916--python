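"""Read/write adapters for BED, FASTA, JASPAR PWMs, and TSV tables.

Coordinates are 0-based half-open on disk and in memory (native BED).
Tables are UTF-8 TSV with a header row; the missing marker per file is
documented where it applies (peptide tables use the empty string). All
writers accept an optional comment header (used to record seeds), emitted as
``#``-prefixed lines that readers skip.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import PWM


def _write_comments(fh, comments) -> None:
    for line in comments or []:
        fh.write(f"# {line}\n")


# ----------------------------------------------------------------------- BED

def write_bed(df: pd.DataFrame, path: str, comments=None) -> None:
    """Write BED6 (chrom, start, end, name, score, strand)."""
    out = df.copy()
    if "score" not in out.columns:
        out["score"] = 0
    if "strand" not in out.columns:
        out["strand"] = "."
    name_col = "peak_id" if "peak_id" in out.columns else "name"
    with open(path, "w") as fh:
        _write_comments(fh, comments)
        for row in out.itertuples(index=False):
            d = row._asdict()
            fh.write(
                f"{d['chrom']}\t{int(d['start'])}\t{int(d['end'])}\t"
                f"{d[name_col]}\t{d['score']}\t{d['strand']}\n"
            )


def read_bed(path: str, one_based: bool = False) -> pd.DataFrame:
    """Read BED6 into (chrom, start, end, name, score, strand).

    ``one_based=True`` converts closed 1-based intervals ([1,100] -> [0,100)).
    Malformed lines raise with file and line number.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from None
            if one_based:
                start -= 1
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{ln}: invalid interval [{start}, {end})"
                )
            name = parts[3] if len(parts) > 3 else f"feature_{ln}"
            score = parts[4] if len(parts) > 4 else "0"
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((parts[0], start, end, name, score, strand))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


# ----------------------------------------------------------------------- TSV

def write_tsv(df: pd.DataFrame, path: str, comments=None, na_rep: str = "") -> None:
    with open(path, "w") as fh:
        _write_comments(fh, comments)
        df.to_csv(fh, sep="\t", index=False, na_rep=na_rep, lineterminator="\n")


def read_tsv(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# --------------------------------------------------------------------- FASTA

def write_fasta(sequences: dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


# -------------------------------------------------------------------- JASPAR

def write_jaspar(pwms: dict[str, PWM], path: str, scale: int = 100) -> None:
    """Write PWMs as JASPAR-style count matrices (probabilities x scale)."""
    with open(path, "w") as fh:
        for name, pwm in pwms.items():
            fh.write(f">{name}\t{name}\n")
            counts = np.round(pwm.matrix * scale).astype(int)
            for i, base in enumerate("ACGT"):
                vals = "  ".join(str(v) for v in counts[:, i])
                fh.write(f"{base}  [ {vals} ]\n")


def read_jaspar(path: str, threshold_frac: float = 0.8) -> dict[str, PWM]:
    """Parse JASPAR-format PWM text; counts are normalized per position."""
    pwms: dict[str, PWM] = {}
    name = None
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh] + [">"]
    ln_no = 0
    for line in lines:
        ln_no += 1
        if line.startswith(">"):
            if name is not None:
                if set(rows) != set("ACGT"):
                    raise ValueError(
                        f"{path}: motif {name!r} missing base rows "
                        f"{sorted(set('ACGT') - set(rows))}"
                    )
                mat = np.array([rows[b] for b in "ACGT"], dtype=float).T
                sums = mat.sum(axis=1, keepdims=True)
                if (sums <= 0).any():
                    raise ValueError(f"{path}: motif {name!r} has a zero column")
                pwms[name] = PWM(name, mat / sums, threshold_frac=threshold_frac)
            name = line[1:].split()[0] if len(line) > 1 else None
            rows = {}
        elif line.strip():
            base = line.strip()[0].upper()
            if base not in "ACGT":
                raise ValueError(f"{path}:{ln_no}: unexpected row {line!r}")
            nums = line.replace("[", " ").replace("]", " ").split()[1:]
            rows[base] = [float(x) for x in nums]
    return pwms


def convert_one_based(start: int, end: int) -> tuple[int, int]:
    """Closed 1-based [start, end] to half-open 0-based [start-1, end)."""
    return start - 1, end
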