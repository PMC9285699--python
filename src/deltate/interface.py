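"""Command-line entry points and the standard visualisations.

The CLI mirrors the wrapper-script workflow: ``delta-te run`` executes the
whole pipeline and writes a Results/ directory; ``delta-te goi`` draws the
per-gene fold-change line plot from previously written fold-change tables;
``delta-te simulate`` and ``delta-te benchmark`` expose the synthetic-data
generator and the method comparison. Every CLI behaviour is a thin shell
over library functions.
"""

from __future__ import annotations

import json
import os
import sys
from dataclasses import dataclass, fields

import click
import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import dataio, nbglm, simbench
from .dataio import CountMatrix, SampleTable, read_result_table
from .dte import DTEResult, run_delta_te
from .normalization import compute_size_factors, normalize_counts

CLASS_COLORS = {
    "forwarded": "blue",
    "exclusive": "red",
    "intensified": "magenta",
    "buffered": "magenta",
    "buffered_special": "magenta",
}


@dataclass
class PcaSummary:
    coordinates: pd.DataFrame       # samples x PCs
    variance_fractions: np.ndarray  # one per component, sums to 1
    groups: pd.DataFrame            # condition / batch labels per sample


def pca_summary(counts: CountMatrix, sf: pd.Series, samples: SampleTable,
                ntop: int = 500) -> PcaSummary:
    """PCA of log2(normalised counts + 1) on the most variable genes.

    Genes are centred, samples are projected by SVD. Variance fractions are
    over all components and sum to one, so the printed PC1/PC2 percentages
    are directly comparable with standard QC plots.
    """
    frame = normalize_counts(counts, sf)
    if frame.shape[0] < 2:
        raise ValueError("PCA needs at least 2 genes")
    if frame.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    logmat = np.log2(frame.to_numpy() + 1.0)
    var = logmat.var(axis=1)
    top = np.argsort(var)[::-1][: min(ntop, len(var))]
    X = logmat[top]
    X = X - X.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(X.T, full_matrices=False)
    coords = U * S
    tot = (S**2).sum()
    fracs = S**2 / tot if tot > 0 else np.full(len(S), 1.0 / len(S))
    pcs = [f"PC{i + 1}" for i in range(coords.shape[1])]
    coord_df = pd.DataFrame(coords, index=frame.columns, columns=pcs)
    meta = samples.data.set_index("sample_id").reindex(frame.columns)
    return PcaSummary(coord_df, fracs, meta)


def plot_pca(summary: PcaSummary, ax=None, title: str = "PCA"):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    coords = summary.coordinates
    conds = summary.groups["condition"]
    has_batch = "batch" in summary.groups.columns
    markers = ["o", "s", "^", "D", "v", "P"]
    for i, cond in enumerate(sorted(conds.unique())):
        mask = (conds == cond).to_numpy()
        if has_batch:
            batches = summary.groups["batch"]
            for j, b in enumerate(sorted(batches.unique())):
                m = mask & (batches == b).to_numpy()
                ax.scatter(coords.iloc[m, 0], coords.iloc[m, 1],
                           label=f"cond {cond}, batch {b}",
                           marker=markers[j % len(markers)], alpha=0.8)
        else:
            ax.scatter(coords.iloc[mask, 0], coords.iloc[mask, 1],
                       label=f"cond {cond}", alpha=0.8)
    vf = summary.variance_fractions
    ax.set_xlabel(f"PC1 ({100 * vf[0]:.0f}% variance)")
    ax.set_ylabel(f"PC2 ({100 * vf[1]:.0f}% variance)")
    ax.set_title(title)
    ax.legend(fontsize=7)
    return ax


def global_scatter_plot(result: DTEResult, classes: pd.DataFrame,
                        path=None, ax=None):
    """Scatter of ΔRNA (x) versus ΔRPF (y) coloured by regulatory class.

    Axes are symmetric about zero with equal aspect; the identity line marks
    purely forwarded behaviour.
    """
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 5))
    else:
        fig = ax.figure
    x = result.rna["log2FoldChange"]
    y = result.rpf["log2FoldChange"]
    finite = x.notna() & y.notna()
    lim = float(np.nanmax(np.abs(np.r_[x[finite], y[finite]]))) if finite.any() else 1.0
    ax.scatter(x[finite], y[finite], s=6, color="grey", alpha=0.25, lw=0)
    labels = classes["class"].reindex(x.index)
    for cls, color in CLASS_COLORS.items():
        m = finite & (labels == cls)
        if m.any():
            ax.scatter(x[m], y[m], s=8, color=color, lw=0,
                       label=cls.replace("_", " "))
    ax.axline((0, 0), slope=1, color="gray", lw=0.8)
    ax.axhline(0, color="gray", lw=0.8)
    ax.axvline(0, color="gray", lw=0.8)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.set_xlabel("RNA-seq log2 fold change")
    ax.set_ylabel("Ribo-seq log2 fold change")
    if labels.notna().any():
        ax.legend(fontsize=7, loc="upper left")
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return ax


def gene_profile_plot(gene_id: str, result: DTEResult, path=None, ax=None):
    """Line plot of a gene's ΔRNA, ΔRPF and ΔTE from condition 1 to 2."""
    if gene_id not in result.te.index:
        raise KeyError(f"unknown gene id {gene_id!r}")
    vals = {
        "RNA": result.rna.loc[gene_id, "log2FoldChange"],
        "Ribo": result.rpf.loc[gene_id, "log2FoldChange"],
        "TE": result.te.loc[gene_id, "log2FoldChange"],
    }
    for name, v in vals.items():
        if not np.isfinite(v):
            raise ValueError(f"gene {gene_id!r} has no {name} fold change (NA)")
    if ax is None:
        fig, ax = plt.subplots(figsize=(4, 4))
    else:
        fig = ax.figure
    colors = {"RNA": "blue", "Ribo": "gray", "TE": "red"}
    for name, v in vals.items():
        ax.plot([0, 1], [0, v], color=colors[name], label=name)
    ax.set_xticks([0, 1])
    ax.set_xticklabels(list(result.contrast))
    ax.set_ylabel("Log2 fold change")
    ax.set_title(gene_id)
    ax.legend(loc="best", fontsize=8, frameon=False)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return ax


def write_results_figures(exp, result: DTEResult, path) -> None:
    """Results_figures.pdf: per-assay PCA, global scatter, exemplar profiles."""
    from matplotlib.backends.backend_pdf import PdfPages

    with PdfPages(path) as pdf:
        for name, counts in (("Ribo-seq", exp.ribo), ("RNA-seq", exp.rna)):
            sub = exp.samples.subset_seqtype("RIBO" if name == "Ribo-seq" else "RNA")
            sf = compute_size_factors(counts)
            fig, ax = plt.subplots(figsize=(5, 4))
            plot_pca(pca_summary(counts, sf, sub), ax=ax, title=f"PCA: {name}")
            pdf.savefig(fig, bbox_inches="tight")
            plt.close(fig)

        fig, ax = plt.subplots(figsize=(5.5, 5.5))
        global_scatter_plot(result, result.classes, ax=ax)
        pdf.savefig(fig, bbox_inches="tight")
        plt.close(fig)

        # one exemplar per class: the gene with the largest |ΔTE| LFC
        labels = result.classes["class"]
        for cls in ("forwarded", "exclusive", "buffered", "intensified"):
            genes = labels.index[labels.isin(
                [cls, "buffered_special"] if cls == "buffered" else [cls])]
            if len(genes) == 0:
                continue
            te_lfc = result.te.loc[genes, "log2FoldChange"].abs()
            if cls == "forwarded":  # TE ~ 0 by construction; rank by ΔRNA
                te_lfc = result.rna.loc[genes, "log2FoldChange"].abs()
            top = te_lfc.idxmax()
            fig, ax = plt.subplots(figsize=(4, 4))
            gene_profile_plot(top, result, ax=ax)
            ax.set_title(f"{cls}: {top}")
            pdf.savefig(fig, bbox_inches="tight")
            plt.close(fig)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
def main():
    """Detect and classify differential translation efficiency genes."""


@main.command("run")
@click.argument("ribo_path", type=click.Path(exists=True))
@click.argument("rna_path", type=click.Path(exists=True))
@click.argument("samples_path", type=click.Path(exists=True))
@click.argument("batch_flag", type=click.IntRange(0, 1))
@click.argument("save_state_flag", type=click.IntRange(0, 1), default=1, required=False)
@click.argument("verbose_flag", type=click.IntRange(0, 1), default=0, required=False)
@click.option("--outdir", default="Results", show_default=True,
              help="Output directory.")
@click.option("--alpha", default=0.05, show_default=True,
              help="FDR threshold for significance calls.")
def cli_run(ribo_path, rna_path, samples_path, batch_flag, save_state_flag,
            verbose_flag, outdir, alpha):
    """Full pipeline: RIBO counts, RNA counts, sample table, batch 0|1,
    [save-state 0|1] [verbose 0|1]."""
    def log(msg):
        if verbose_flag:
            click.echo(msg, err=True)

    try:
        ribo = dataio.read_count_matrix(ribo_path)
        rna = dataio.read_count_matrix(rna_path)
        samples = dataio.read_sample_table(samples_path)
        if batch_flag and not samples.has_batch:
            raise dataio.DataValidationError(
                "batch covariate requested (argument 4 = 1) but the sample "
                "table has no Batch column")
        exp = dataio.validate_experiment(ribo, rna, samples)
        log(f"validated {len(exp.common_genes)} genes, "
            f"{len(samples.sample_ids)} samples")
        result = run_delta_te(exp, with_batch=bool(batch_flag), alpha=alpha,
                              outdir=outdir)
    except (ValueError, FileNotFoundError, nbglm.DesignError) as exc:
        click.echo(f"error: {exc}", err=True)
        sys.exit(1)
    click.echo(result.class_counts.to_string())
    if save_state_flag:
        state = {
            "alpha": alpha,
            "with_batch": bool(batch_flag),
            "contrast": list(result.contrast),
            "n_genes": len(result.genes),
            "class_counts": {k: int(v) for k, v in result.class_counts.items()},
        }
        with open(os.path.join(outdir, "run_state.json"), "w") as fh:
            json.dump(state, fh, indent=2)
        log(f"run state saved to {outdir}/run_state.json")


@main.command("goi")
@click.argument("ribo_fc", type=click.Path(exists=True))
@click.argument("rna_fc", type=click.Path(exists=True))
@click.argument("te_fc", type=click.Path(exists=True))
@click.argument("gene_id")
@click.option("--out", default=None, help="Output plot path [GENE_ID.pdf].")
def cli_goi(ribo_fc, rna_fc, te_fc, gene_id, out):
    """Gene-of-interest line plot from three fold-change tables."""
    try:
        result = DTEResult(te=read_result_table(te_fc),
                           rna=read_result_table(rna_fc),
                           rpf=read_result_table(ribo_fc))
        gene_profile_plot(gene_id, result, path=out or f"{gene_id}.pdf")
    except (KeyError, ValueError, FileNotFoundError) as exc:
        click.echo(f"error: {exc}", err=True)
        sys.exit(1)


def _parse_config(path, seed) -> simbench.SimConfig:
    """Key=value config file -> SimConfig (tuples comma-separated)."""
    kwargs = {}
    valid = {f.name: f.type for f in fields(simbench.SimConfig)}
    if path is not None:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in valid:
                    raise ValueError(f"unknown simulation parameter {key!r}")
                value = value.strip()
                if "," in value:
                    kwargs[key] = tuple(float(v) for v in value.split(","))
                elif key in ("n_genes", "reps_per_cell", "n_batches", "seed"):
                    kwargs[key] = int(value)
                else:
                    kwargs[key] = float(value)
    if seed is not None:
        kwargs["seed"] = int(seed)
    return simbench.SimConfig(**kwargs)


@main.command("simulate")
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None, help="key=value simulation parameter file.")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--outdir", default="simulated", show_default=True)
def cli_simulate(config_path, seed, outdir):
    """Write a simulated dataset (counts, sample table, truth) as TSV."""
    try:
        cfg = _parse_config(config_path, seed)
        ribo, rna, samples, truth = simbench.simulate_dataset(cfg)
    except ValueError as exc:
        click.echo(f"error: {exc}", err=True)
        sys.exit(1)
    os.makedirs(outdir, exist_ok=True)
    ribo.to_frame().rename_axis("Gene ID").to_csv(
        os.path.join(outdir, "ribo_counts.txt"), sep="\t")
    rna.to_frame().rename_axis("Gene ID").to_csv(
        os.path.join(outdir, "rna_counts.txt"), sep="\t")
    samples.data.rename(columns={"sample_id": "SampleID",
                                 "condition": "Condition",
                                 "seqtype": "SeqType",
                                 "batch": "Batch"}).to_csv(
        os.path.join(outdir, "sample_info.txt"), sep="\t", index=False)
    truth.rename_axis("gene_id").to_csv(
        os.path.join(outdir, "truth.txt"), sep="\t")
    click.echo(f"simulated {cfg.n_genes} genes -> {outdir}/")


@main.command("benchmark")
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None, help="key=value simulation parameter file.")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--alpha", default=0.05, show_default=True)
@click.option("--out", default="benchmark.tsv", show_default=True)
def cli_benchmark(config_path, seed, alpha, out):
    """Simulate and compare ΔTE against the Ratio and Overlap baselines."""
    try:
        cfg = _parse_config(config_path, seed)
        table = simbench.run_benchmark(cfg, alpha=alpha)
    except ValueError as exc:
        click.echo(f"error: {exc}", err=True)
        sys.exit(1)
    table.rename_axis("method").to_csv(out, sep="\t", float_format="%.4f")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(table.index, table["accuracy"], color="steelblue")
    ax.set_ylabel(f"accuracy at the working threshold (alpha={alpha})")
    ax.set_ylim(0, 1)
    ax.tick_params(axis="x", rotation=30)
    fig.savefig(f"{out}.png", bbox_inches="tight")
    plt.close(fig)
    click.echo(table.to_string(float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
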