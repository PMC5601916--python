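"""Pipeline orchestration: staged execution, file layout, and run manifest.

Six stages (simulate, interactome, cistrome, motifs, expression, integrate)
communicate only through files in the run directory, so any suffix of the
pipeline can be re-run from existing intermediates. The manifest records the
configuration snapshot, the seed, and SHA-256 hashes of every stage's inputs
and outputs; identical configurations reproduce identical manifests
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .cistrome import (
    Cistrome,
    PEAK_COLUMNS,
    classify_dependency,
    correlate_cistromes,
    filter_on_knockout,
    filter_peaks,
    overlap_cistromes,
    triple_intersection,
    venn_counts,
)
from .expression import CountMatrix, call_coregulation, de_test
from .integration import (
    assign_gene_window,
    assign_nearest_gene,
    association_test,
    build_gene_flags,
)
from .interactome import score_interactome
from .ioutils import (
    read_bed,
    read_fasta,
    read_jaspar,
    read_tsv,
    write_bed,
    write_fasta,
    write_jaspar,
    write_tsv,
)
from .motifs import compare_motif_enrichment, motif_frequency
from .synthetic import (
    SyntheticTruth,
    simulate_cistromes,
    simulate_expression,
    simulate_genes,
    simulate_proteomics,
)

log = logging.getLogger("corepressor_map")

STAGES = ("simulate", "interactome", "cistrome", "motifs", "expression", "integrate")

FACTORS = ("A", "B", "C")
CONDITIONS = ("control", "ko")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _peaks_bed_name(factor: str, condition: str) -> str:
    return f"peaks_{factor}_{condition}.bed"


# ------------------------------------------------------------------- stages

def stage_simulate(cfg: PipelineConfig, outdir: Path) -> tuple[list[str], list[str]]:
    sim = cfg.sim
    header = [f"seed={sim.seed}", f"generator=corepressor-map {__version__}"]

    peptides, proteins, truth_p = simulate_proteomics(sim)
    write_tsv(peptides, outdir / "peptides.tsv", comments=header)
    write_fasta(proteins, outdir / "proteins.fasta")

    cistromes, genome, pwms, truth_c = simulate_cistromes(sim)
    for (factor, condition), cis in cistromes.items():
        write_bed(cis.peaks, outdir / _peaks_bed_name(factor, condition),
                  comments=header)
    signal = pd.concat(
        [
            cis.peaks[["peak_id", "reads", "input_reads"]].assign(
                factor=factor,
                condition=condition,
                library_size=cis.library_size,
            )
            for (factor, condition), cis in cistromes.items()
        ]
    )[["peak_id", "factor", "condition", "reads", "library_size", "input_reads"]]
    write_tsv(signal, outdir / "signal.tsv", comments=header)
    write_fasta(genome, outdir / "genome.fa")
    write_jaspar(pwms, outdir / "pwms.jaspar")

    genes = simulate_genes(sim)
    write_tsv(genes, outdir / "genes.tsv", comments=header)

    # genes adjacent to truth dependent co-bound sites seed the expression plant
    dep_peaks = _dependent_peak_intervals(cistromes, truth_c.dependent_peaks)
    links = assign_gene_window(
        dep_peaks, genes, cfg.thresholds.window_upstream,
        cfg.thresholds.window_downstream,
    )
    cm, truth_e = simulate_expression(sim, genes, set(links["gene_id"]))
    counts_out = cm.counts.reset_index()
    write_tsv(counts_out, outdir / "counts.tsv", comments=header)
    write_tsv(cm.samples.reset_index(), outdir / "samples.tsv", comments=header)

    truth = truth_p.merged_with(truth_c).merged_with(truth_e)
    (outdir / "truth.json").write_text(truth.to_json() + "\n")

    outputs = (
        ["peptides.tsv", "proteins.fasta", "signal.tsv", "genome.fa",
         "pwms.jaspar", "genes.tsv", "counts.tsv", "samples.tsv", "truth.json"]
        + [_peaks_bed_name(f, c) for f in FACTORS for c in CONDITIONS]
    )
    return [], outputs


def _dependent_peak_intervals(cistromes, dependent_ids) -> pd.DataFrame:
    frames = []
    for factor in ("A", "B"):
        p = cistromes[(factor, "control")].peaks
        frames.append(p[p["peak_id"].isin(dependent_ids)])
    if not frames:
        return pd.DataFrame(columns=["peak_id", "chrom", "start", "end"])
    return pd.concat(frames)[["peak_id", "chrom", "start", "end"]].reset_index(
        drop=True
    )


def stage_interactome(cfg: PipelineConfig, outdir: Path):
    t = cfg.thresholds
    peptides = read_tsv(outdir / "peptides.tsv")
    proteins = read_fasta(outdir / "proteins.fasta")
    results = score_interactome(
        peptides,
        proteins,
        fold_cutoff=t.interactor_fold,
        p_cutoff=t.interactor_p,
        benzonase_fold=t.benzonase_fold,
        width=cfg.impute_width,
        downshift=cfg.impute_downshift,
        seed=cfg.sim.seed,
    )
    untreated = results["none"]
    classes = results["nuclease_classes"].set_index("protein_id")["nuclease_class"]
    table = untreated.assign(
        nuclease_class=untreated["protein_id"].map(classes).fillna("")
    )[
        ["protein_id", "n_peptides", "log2_enrichment", "p_value", "adj_p",
         "is_interactor", "nuclease_class"]
    ]
    write_tsv(table, outdir / "interactome.tsv")
    volcano = untreated.assign(
        neg_log10_p=-np.log10(untreated["p_value"].clip(lower=1e-300))
    )[["protein_id", "log2_enrichment", "neg_log10_p"]]
    write_tsv(volcano, outdir / "volcano.tsv")
    return ["peptides.tsv", "proteins.fasta"], ["interactome.tsv", "volcano.tsv"]


def load_cistrome(outdir: Path, factor: str, condition: str) -> Cistrome:
    bed = read_bed(outdir / _peaks_bed_name(factor, condition))
    signal = read_tsv(outdir / "signal.tsv")
    sig = signal[(signal["factor"] == factor) & (signal["condition"] == condition)]
    sig = sig.set_index("peak_id")
    df = pd.DataFrame(
        {
            "peak_id": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"],
            "end": bed["end"],
            "reads": sig.loc[bed["name"], "reads"].to_numpy(),
            "input_reads": sig.loc[bed["name"], "input_reads"].to_numpy(),
        }
    )
    lib = int(sig["library_size"].iloc[0])
    return Cistrome(factor, condition, df, lib)


def stage_cistrome(cfg: PipelineConfig, outdir: Path):
    t = cfg.thresholds
    inputs = [_peaks_bed_name(f, c) for f in FACTORS for c in CONDITIONS]
    inputs.append("signal.tsv")
    cis = {
        (f, c): load_cistrome(outdir, f, c) for f in FACTORS for c in CONDITIONS
    }
    a = filter_peaks(cis[("A", "control")], t.min_rpm_a, t.input_fold)
    b = filter_peaks(cis[("B", "control")], t.min_rpm_b, t.input_fold)
    part = overlap_cistromes(a, b, t.min_overlap_frac, t.min_other_rpm)

    venn = venn_counts(part)
    (outdir / "venn.json").write_text(json.dumps(
        {"convention": "co_bound counts co-bound A-side peaks once each", **venn},
        indent=2, sort_keys=True) + "\n")

    classes = pd.concat(
        [
            a.peaks[a.peaks["peak_id"].isin(part.co_a)].assign(klass="co_bound"),
            a.peaks[a.peaks["peak_id"].isin(part.a_only)].assign(klass="a_only"),
            b.peaks[b.peaks["peak_id"].isin(part.b_only)].assign(klass="b_only"),
        ]
    )
    # partition BED: class label in column 4, peak id in column 5
    with open(outdir / "partition.bed", "w") as fh:
        for chrom, start, end, klass, pid in zip(
            classes["chrom"], classes["start"], classes["end"],
            classes["klass"], classes["peak_id"],
        ):
            fh.write(f"{chrom}\t{start}\t{end}\t{klass}\t{pid}\t.\n")

    c_filtered = filter_peaks(cis[("C", "control")], t.min_rpm_c, t.input_fold)
    c_ko = cis[("C", "ko")]
    ko_matched = Cistrome(
        c_ko.factor,
        c_ko.condition,
        c_ko.peaks[c_ko.peaks["peak_id"].isin(c_filtered.peaks["peak_id"])][
            list(PEAK_COLUMNS)
        ].reset_index(drop=True),
        c_ko.library_size,
    )
    c_specific = filter_on_knockout(c_filtered, ko_matched, t.ko_persist_frac)
    triple = triple_intersection(part, a, b, c_specific, t.min_overlap_frac)
    (outdir / "triple.json").write_text(
        json.dumps(
            {
                "fractions": triple["fractions"],
                "counts": triple["counts"],
                "tests": triple["tests"],
                "triple_bound": sorted(triple["triple_bound"]),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )

    dep_frames = []
    for factor, filtered in (("A", a), ("B", b)):
        ko = cis[(factor, "ko")]
        ko_sub = Cistrome(
            factor,
            "ko",
            ko.peaks[ko.peaks["peak_id"].isin(filtered.peaks["peak_id"])][
                list(PEAK_COLUMNS)
            ].reset_index(drop=True),
            ko.library_size,
        )
        calls = classify_dependency(
            filtered, ko_sub, t.dependency_fold, t.rpm_pseudocount
        )
        dep_frames.append(calls.assign(factor=factor))
    dependency = pd.concat(dep_frames, ignore_index=True)
    write_tsv(dependency, outdir / "dependency.tsv")

    r = correlate_cistromes(a, b)
    (outdir / "correlation.json").write_text(
        json.dumps({"pearson_r": r, "n_union_peaks": None}, indent=2, sort_keys=True)
        + "\n"
    )
    outputs = ["venn.json", "partition.bed", "triple.json", "dependency.tsv",
               "correlation.json"]
    return inputs, outputs


def _read_partition_classes(outdir: Path) -> dict[str, pd.DataFrame]:
    rows = []
    with open(outdir / "partition.bed") as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, klass, pid, _ = line.rstrip("\n").split("\t")
            rows.append((chrom, int(start), int(end), klass, pid))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "klass", "peak_id"])
    return {k: g.drop(columns="klass").reset_index(drop=True)
            for k, g in df.groupby("klass")}


def stage_motifs(cfg: PipelineConfig, outdir: Path):
    t = cfg.thresholds
    genome = read_fasta(outdir / "genome.fa")
    pwms = read_jaspar(outdir / "pwms.jaspar", t.motif_threshold_frac)
    classes = _read_partition_classes(outdir)

    freq_rows, cmp_rows = [], []
    for pwm_name, pwm in sorted(pwms.items()):
        for klass, peaks in sorted(classes.items()):
            f = motif_frequency(peaks, genome, pwm, t.motif_window)
            freq_rows.append(
                {"class": klass, "pwm": pwm_name, "n": f["n"], "hits": f["hits"],
                 "fraction": f["fraction"]}
            )
        for other in ("a_only", "b_only"):
            if "co_bound" not in classes or other not in classes:
                continue
            cmpres = compare_motif_enrichment(
                classes["co_bound"], classes[other], genome, pwm, t.motif_window,
                labels=("co_bound", other),
            )
            cmp_rows.append(
                {
                    "classA": "co_bound",
                    "classB": other,
                    "pwm": pwm_name,
                    "chi2": cmpres["chi2"],
                    "p": cmpres["p"],
                    "method": cmpres["method"],
                }
            )
    write_tsv(pd.DataFrame(freq_rows), outdir / "motif_freq.tsv")
    write_tsv(pd.DataFrame(cmp_rows), outdir / "motif_compare.tsv")
    return (
        ["genome.fa", "pwms.jaspar", "partition.bed"],
        ["motif_freq.tsv", "motif_compare.tsv"],
    )


def load_count_matrix(outdir: Path) -> CountMatrix:
    counts = read_tsv(outdir / "counts.tsv").set_index("gene_id")
    samples = read_tsv(outdir / "samples.tsv").set_index("sample_id")
    return CountMatrix(counts, samples.loc[counts.columns])


def stage_expression(cfg: PipelineConfig, outdir: Path):
    t = cfg.thresholds
    cm = load_count_matrix(outdir)
    de_a = de_test(cm, "A", t.de_fold, t.de_p)
    de_b = de_test(cm, "B", t.de_fold, t.de_p)
    write_tsv(de_a, outdir / "de_A.tsv")
    write_tsv(de_b, outdir / "de_B.tsv")
    coreg = call_coregulation(de_a, de_b)
    write_tsv(coreg.directions, outdir / "coregulation.tsv")
    (outdir / "coregulation.json").write_text(
        json.dumps(
            {
                "n_correlated": len(coreg.correlated),
                "n_anti_correlated": len(coreg.anti_correlated),
                "overlap_odds": coreg.overlap_odds,
                "overlap_p": coreg.overlap_p,
                "overlap_table": coreg.overlap_table.tolist(),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return (
        ["counts.tsv", "samples.tsv"],
        ["de_A.tsv", "de_B.tsv", "coregulation.tsv", "coregulation.json"],
    )


def stage_integrate(cfg: PipelineConfig, outdir: Path):
    t = cfg.thresholds
    genes = read_tsv(outdir / "genes.tsv")
    dependency = read_tsv(outdir / "dependency.tsv")
    classes = _read_partition_classes(outdir)
    coreg = read_tsv(outdir / "coregulation.tsv")

    cobound = classes.get("co_bound", pd.DataFrame(
        columns=["chrom", "start", "end", "peak_id"]))
    lost_ids = set(dependency.loc[dependency["status"] == "lost", "peak_id"])
    dep_cobound = cobound[cobound["peak_id"].isin(lost_ids)]

    links = assign_gene_window(
        dep_cobound, genes, t.window_upstream, t.window_downstream
    )
    write_tsv(links, outdir / "links.tsv")
    nearest = assign_nearest_gene(cobound, genes, t.nearest_max_dist)
    write_tsv(nearest, outdir / "links_nearest.tsv")

    flags = build_gene_flags(genes, links, coreg)
    result = association_test(flags)
    (outdir / "association.json").write_text(
        json.dumps(
            {
                "table": result.table.tolist(),
                "chi2": result.chi2,
                "p": result.p,
                "n_genes": result.n_genes,
                "convention": "tss50k_tes2k",
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return (
        ["genes.tsv", "dependency.tsv", "partition.bed", "coregulation.tsv"],
        ["links.tsv", "links_nearest.tsv", "association.json"],
    )


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "interactome": stage_interactome,
    "cistrome": stage_cistrome,
    "motifs": stage_motifs,
    "expression": stage_expression,
    "integrate": stage_integrate,
}


def run_all(cfg: PipelineConfig, stages=None) -> dict:
    """Run the pipeline (or a subset of stages) and write the run manifest.

    Returns the manifest dict. Stages read their inputs from the run
    directory, so re-running a suffix of the stage list on existing
    intermediates reproduces identical downstream outputs.
    """
    cfg.validate()
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = {
        "package_version": __version__,
        "seed": cfg.sim.seed,
        "config": cfg.to_dict(),
        "stages": [],
    }
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        try:
            inputs, outputs = _STAGE_FUNCS[stage](cfg, outdir)
        except FileNotFoundError as exc:
            raise RuntimeError(
                f"stage {stage!r} missing upstream output: {exc.filename}"
            ) from exc
        log.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)
        manifest["stages"].append(
            {
                "name": stage,
                "inputs": {f: _sha256(outdir / f) for f in sorted(inputs)},
                "outputs": {f: _sha256(outdir / f) for f in sorted(outputs)},
            }
        )
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
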