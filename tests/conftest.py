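import numpy as np
import pandas as pd
import pytest

from deltate.dataio import SampleTable, validate_experiment
from deltate.simbench import SimConfig, simulate_dataset


@pytest.fixture
def two_by_two_samples():
    """2 conditions x 2 seqtypes x 2 replicates, no batch."""
    return SampleTable(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(8)],
        "condition": ["1", "1", "2", "2"] * 2,
        "seqtype": ["RIBO"] * 4 + ["RNA"] * 4,
    }))


@pytest.fixture
def batched_samples():
    """A typical 8-sample table: 2 conditions, 2 batches, crossed."""
    return SampleTable(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(8)],
        "condition": ["1", "1", "2", "2"] * 2,
        "seqtype": ["RIBO"] * 4 + ["RNA"] * 4,
        "batch": ["1", "2", "1", "2"] * 2,
    }))


@pytest.fixture(scope="session")
def mixed_class_dataset():
    """A small simulated experiment containing every regulatory class."""
    cfg = SimConfig(n_genes=150, reps_per_cell=4,
                    frac_forwarded=0.12, frac_exclusive=0.12,
                    frac_intensified=0.08, frac_buffered=0.08,
                    frac_buffered_special=0.04,
                    base_mean_min=100.0, seed=42)
    ribo, rna, samples, truth = simulate_dataset(cfg)
    return ribo, rna, samples, truth


@pytest.fixture(scope="session")
def mixed_class_experiment(mixed_class_dataset):
    ribo, rna, samples, _ = mixed_class_dataset
    return validate_experiment(ribo, rna, samples)


def write_experiment_tsvs(tmpdir, ribo, rna, samples):
    """Write a simulated experiment as the three standard input files."""
    ribo_path = tmpdir / "ribo_counts.txt"
    rna_path = tmpdir / "rna_counts.txt"
    samples_path = tmpdir / "sample_info.txt"
    ribo.to_frame().rename_axis("Gene ID").to_csv(ribo_path, sep="\t")
    rna.to_frame().rename_axis("Gene ID").to_csv(rna_path, sep="\t")
    samples.data.rename(columns={
        "sample_id": "SampleID", "condition": "Condition",
        "seqtype": "SeqType", "batch": "Batch"}).to_csv(
        samples_path, sep="\t", index=False)
    return ribo_path, rna_path, samples_path
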