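"""Reading, validation and writing of the tabular inputs and outputs.

The analysis consumes two raw count matrices (genes x samples; one for
ribosome-protected-fragment counts, one for mRNA counts) and a sample table
assigning each sample a condition, a sequencing type (RIBO or RNA) and an
optional batch. Counts must be raw, non-negative integers: normalisation
happens downstream via size factors, never in the input files.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEQTYPES = ("RIBO", "RNA")

#: classes that get a gene-list file; the special-case buffered genes are
#: merged into buffered.txt but keep their own label in memory
GENE_LIST_CLASSES = ("forwarded", "exclusive", "intensified", "buffered", "undetermined")

RESULT_COLUMNS = ["baseMean", "log2FoldChange", "lfcSE", "stat", "pvalue", "padj"]


class DataValidationError(ValueError):
    """Raised when an input file violates a structural invariant."""


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts."""

    gene_ids: list
    sample_ids: list
    counts: np.ndarray

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise DataValidationError("counts must be a 2-D array")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise DataValidationError(f"duplicate gene id: {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise DataValidationError(f"duplicate sample id: {dup!r}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_float = self.counts.astype(float)
            if not np.all(np.isfinite(as_float)) or np.any(as_float != np.round(as_float)):
                g, s = _first_bad_cell(as_float, lambda v: not np.isfinite(v) or v != round(v))
                raise DataValidationError(
                    f"non-integer count {as_float[g, s]!r} for gene "
                    f"{self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
                )
            self.counts = as_float.astype(np.int64)
        if np.any(self.counts < 0):
            g, s = _first_bad_cell(self.counts, lambda v: v < 0)
            raise DataValidationError(
                f"negative count {self.counts[g, s]} for gene "
                f"{self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.copy(), index=list(self.gene_ids),
                            columns=list(self.sample_ids))

    def subset_genes(self, gene_ids) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return CountMatrix(list(gene_ids), list(self.sample_ids), self.counts[rows])

    def subset_samples(self, sample_ids) -> "CountMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, cols])

    def hstack(self, other: "CountMatrix") -> "CountMatrix":
        if list(other.gene_ids) != list(self.gene_ids):
            raise DataValidationError("gene ids differ; validate the experiment first")
        return CountMatrix(list(self.gene_ids),
                           list(self.sample_ids) + list(other.sample_ids),
                           np.hstack([self.counts, other.counts]))


@dataclass
class SampleTable:
    """Per-sample metadata: condition, sequencing type, optional batch."""

    data: pd.DataFrame  # columns: sample_id, condition, seqtype, [batch]

    def __post_init__(self):
        df = self.data.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["condition"] = df["condition"].astype(str)
        df["seqtype"] = df["seqtype"].astype(str).str.upper()
        if "batch" in df.columns:
            df["batch"] = df["batch"].astype(str)
        bad = sorted(set(df["seqtype"]) - set(SEQTYPES))
        if bad:
            raise DataValidationError(
                f"unknown SeqType value(s) {bad}; allowed values are {list(SEQTYPES)}"
            )
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise DataValidationError(f"duplicate sample id: {dup!r}")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return list(self.data["sample_id"])

    @property
    def conditions(self) -> list:
        return sorted(self.data["condition"].unique())

    @property
    def has_batch(self) -> bool:
        return "batch" in self.data.columns

    def subset_seqtype(self, seqtype: str) -> "SampleTable":
        sub = self.data[self.data["seqtype"] == seqtype.upper()]
        return SampleTable(sub.copy())

    def check_replication(self) -> None:
        """Enforce >= 2 samples per (condition, seqtype) cell; warn below 3."""
        sizes = self.data.groupby(["condition", "seqtype"]).size()
        for (cond, seq), n in sizes.items():
            if n < 2:
                raise DataValidationError(
                    f"only {n} replicate(s) for condition {cond!r}, seqtype {seq}; "
                    "at least 2 are required to estimate dispersion"
                )
            if n < 3:
                warnings.warn(
                    f"only {n} replicates for condition {cond!r}, seqtype {seq}; "
                    "at least three biological replicates per condition are recommended",
                    UserWarning, stacklevel=3,
                )


@dataclass
class ValidatedExperiment:
    """A consistent (ribo, rna, samples) triple sharing one gene order."""

    ribo: CountMatrix
    rna: CountMatrix
    samples: SampleTable
    common_genes: list = field(default_factory=list)


def _first_duplicate(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def _first_bad_cell(arr, pred):
    for g in range(arr.shape[0]):
        for s in range(arr.shape[1]):
            if pred(arr[g, s]):
                return g, s
    raise AssertionError("no offending cell found")


def read_count_matrix(path, delimiter: str = "\t") -> CountMatrix:
    """Read a header-ed genes-x-samples count table.

    The first column holds gene ids, the header row holds sample ids.
    Values must parse as non-negative integers.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"count matrix file not found: {path}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise DataValidationError(f"no genes in count matrix {path}")
    if df.shape[1] == 0:
        raise DataValidationError(f"no samples in count matrix {path}")
    values = np.empty(df.shape, dtype=np.int64)
    for j, sample in enumerate(df.columns):
        col = df.iloc[:, j]
        numeric = pd.to_numeric(col, errors="coerce")
        bad = numeric.isna() | (numeric != np.floor(numeric)) | (numeric < 0)
        if bad.any():
            gene = col.index[bad.argmax()]
            raise DataValidationError(
                f"invalid count {col[bad].iloc[0]!r} for gene {gene!r}, "
                f"sample {sample!r}: counts must be non-negative integers"
            )
        values[:, j] = numeric.astype(np.int64)
    return CountMatrix(list(df.index), list(df.columns), values)


_COLUMN_ALIASES = {
    "sampleid": "sample_id", "sample id": "sample_id", "sample_id": "sample_id",
    "condition": "condition",
    "seqtype": "seqtype", "seq type": "seqtype",
    "batch": "batch",
}


def read_sample_table(path) -> SampleTable:
    """Read the tab-separated sample information file.

    Required columns: SampleID, Condition, SeqType (case-insensitive header
    match). A Batch column is captured when present. SeqType values are
    canonicalised to upper case RIBO/RNA.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"sample table file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _COLUMN_ALIASES:
            rename[col] = _COLUMN_ALIASES[key]
    df = df.rename(columns=rename)
    missing = {"sample_id", "condition", "seqtype"} - set(df.columns)
    if missing:
        raise DataValidationError(
            f"sample table {path} is missing required column(s): {sorted(missing)} "
            "(expected SampleID, Condition, SeqType)"
        )
    keep = ["sample_id", "condition", "seqtype"] + (["batch"] if "batch" in df.columns else [])
    return SampleTable(df[keep])


def validate_experiment(ribo: CountMatrix, rna: CountMatrix, samples: SampleTable,
                        strict_genes: bool = True) -> ValidatedExperiment:
    """Reconcile the two count matrices with the sample table.

    Checks sample-id correspondence, gene-set agreement (strict: error on any
    mismatch; lenient: intersect with a warning), replication per design cell,
    and batch/condition confounding, which would make the batch-corrected
    design non-full-rank.
    """
    ribo_samples = set(samples.subset_seqtype("RIBO").sample_ids)
    rna_samples = set(samples.subset_seqtype("RNA").sample_ids)
    if set(ribo.sample_ids) != ribo_samples:
        raise DataValidationError(
            "RIBO sample ids in the count matrix do not match the sample table: "
            f"matrix has {sorted(ribo.sample_ids)}, table has {sorted(ribo_samples)}"
        )
    if set(rna.sample_ids) != rna_samples:
        raise DataValidationError(
            "RNA sample ids in the count matrix do not match the sample table: "
            f"matrix has {sorted(rna.sample_ids)}, table has {sorted(rna_samples)}"
        )
    samples.check_replication()

    if list(ribo.gene_ids) != list(rna.gene_ids):
        ribo_set, rna_set = set(ribo.gene_ids), set(rna.gene_ids)
        if strict_genes and ribo_set != rna_set:
            extra = sorted((ribo_set ^ rna_set))[:5]
            raise DataValidationError(
                f"gene sets differ between assays (e.g. {extra}); "
                "use strict_genes=False to intersect"
            )
        common = [g for g in ribo.gene_ids if g in rna_set]
        if not common:
            raise DataValidationError("gene intersection between assays is empty")
        dropped = sorted((ribo_set | rna_set) - set(common))
        if dropped:
            warnings.warn(
                f"dropping {len(dropped)} gene(s) absent from one assay: "
                f"{dropped[:5]}", UserWarning, stacklevel=2,
            )
        ribo = ribo.subset_genes(common)
        rna = rna.subset_genes(common)

    if samples.has_batch:
        df = samples.data
        if df["batch"].nunique() > 1:
            per_cond = df.groupby("condition")["batch"].nunique()
            if (per_cond == 1).all():
                raise DataValidationError(
                    "non-full-rank design: batch is completely confounded with "
                    "condition (each condition level sits in a single batch)"
                )
    return ValidatedExperiment(ribo, rna, samples, list(ribo.gene_ids))


def write_result_table(result: pd.DataFrame, path) -> None:
    """Write a per-gene result table in the standard DE output layout.

    Columns: gene_id, baseMean, log2FoldChange, lfcSE, stat, pvalue, padj.
    Missing values are written as NA; floats keep 6 significant digits.
    """
    df = result[RESULT_COLUMNS].copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def read_result_table(path) -> pd.DataFrame:
    """Read back a table produced by :func:`write_result_table`."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def write_gene_lists(classes: pd.Series, outdir) -> dict:
    """Write one gene-id-per-line file per regulatory class.

    ``classes`` maps gene id -> class label. Special-case buffered genes are
    appended to buffered.txt; genes with label ``no_change`` are not listed.
    Empty class files are still created so the directory layout is stable.
    """
    os.makedirs(outdir, exist_ok=True)
    written = {}
    merged = classes.replace({"buffered_special": "buffered"})
    for cls in GENE_LIST_CLASSES:
        genes = list(merged.index[merged == cls])
        fname = os.path.join(outdir, f"{cls}.txt")
        with open(fname, "w") as fh:
            for g in genes:
                fh.write(f"{g}\n")
        written[cls] = fname
    return written


def write_size_factors(sf: pd.Series, path) -> None:
    df = sf.rename("size_factor").to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.6g")
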