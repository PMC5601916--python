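import numpy as np
import pandas as pd
import pytest

from corepressor_map.config import PipelineConfig, SimConfig, Thresholds


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_sim_config():
    """A fast, fully featured study for pipeline-level tests."""
    return SimConfig(
        seed=11,
        n_proteins=80,
        n_true_interactors=8,
        n_dna_bridged=3,
        n_bait_samples=4,
        n_control_samples=4,
        protein_length_range=(80, 200),
        genome=(("chr1", 3_000_000), ("chr2", 3_000_000)),
        n_peaks_per_factor=60,
        n_genes=120,
    )


@pytest.fixture
def small_pipeline_config(small_sim_config, tmp_path):
    return PipelineConfig(
        sim=small_sim_config,
        thresholds=Thresholds(),
        outdir=str(tmp_path / "run"),
    )


def quant_matrix(values, conditions, nuclease="none"):
    """Build a ProteinQuantMatrix from a 2-D array for unit tests."""
    from corepressor_map.interactome import ProteinQuantMatrix

    values = np.asarray(values, dtype=float)
    sample_ids = [f"s{j}" for j in range(values.shape[1])]
    samples = pd.DataFrame(
        {"condition": conditions, "nuclease": nuclease},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    vals = pd.DataFrame(
        values,
        index=pd.Index([f"P{i}" for i in range(values.shape[0])], name="protein_id"),
        columns=sample_ids,
    )
    return ProteinQuantMatrix(vals, samples, "raw_ibaq")


def make_cistrome(rows, factor="A", condition="control", library_size=1_000_000):
    """rows: (peak_id, chrom, start, end, reads, input_reads)."""
    from corepressor_map.cistrome import Cistrome

    df = pd.DataFrame(
        rows, columns=["peak_id", "chrom", "start", "end", "reads", "input_reads"]
    )
    return Cistrome(factor, condition, df, library_size)
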