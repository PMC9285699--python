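"""Pipeline orchestration: the three model fits and the result assembly.

Three NB GLMs are fitted per contrast:

* the interaction model on the column-concatenated [ribo | rna] counts with
  design ~ [Batch +] Condition + SeqType + Condition:SeqType, whose
  interaction coefficient is ΔTE;
* an RNA-only model with design ~ [Batch +] Condition giving ΔRNA (DTGs);
* a Ribo-only model of the same form giving ΔRPF.

Each family of p-values is BH-adjusted separately, mirroring three
independent differential-expression runs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify as _classify
from . import nbglm
from .dataio import (CountMatrix, SampleTable, ValidatedExperiment,
                     write_gene_lists, write_result_table)
from .normalization import compute_size_factors

RESULT_COLUMNS = ["baseMean", "log2FoldChange", "lfcSE", "stat", "pvalue", "padj"]


@dataclass
class DTEResult:
    """Per-gene outcome tables for ΔTE, ΔRNA and ΔRPF (aligned gene order)."""

    te: pd.DataFrame
    rna: pd.DataFrame
    rpf: pd.DataFrame
    contrast: tuple = ("1", "2")
    alpha: float = 0.05
    classes: pd.DataFrame | None = None
    class_counts: pd.Series | None = None
    extras: dict = field(default_factory=dict)

    @property
    def genes(self) -> list:
        return list(self.te.index)


def fit_result_table(counts: np.ndarray, gene_ids, design: nbglm.DesignMatrix,
                     sf: np.ndarray, coef_name: str,
                     reduced_design: nbglm.DesignMatrix | None = None
                     ) -> pd.DataFrame:
    """Run the full dispersion pipeline and test one coefficient.

    Per gene: moments initialisation, IRLS fit, Cox-Reid profile dispersion
    MLE, then (across genes) parametric trend fit and empirical-Bayes MAP
    shrinkage, a final IRLS fit at the MAP dispersion, and the Wald test of
    ``coef_name``. When ``reduced_design`` is given a likelihood-ratio test
    of the full against the reduced design (at the shared MAP dispersion)
    replaces the Wald statistic and p-value; the reported LFC/SE still
    describe ``coef_name``. All-zero genes yield NA rows and are excluded
    from the BH family.
    """
    counts = np.asarray(counts)
    sf = np.asarray(sf, dtype=float)
    n_genes = counts.shape[0]
    base_means = np.array([np.mean(row / sf) for row in counts])

    genewise = np.full(n_genes, np.nan)
    mu_matrix = np.zeros((n_genes, counts.shape[1]))
    for g in range(n_genes):
        row = counts[g]
        if np.all(row == 0):
            continue
        a0 = nbglm.moments_dispersion(row, sf)
        fit = nbglm.fit_glm_irls(row, design, sf, a0)
        mu_matrix[g] = fit.mu
        genewise[g], _ = nbglm.profile_dispersion_mle(row, design, sf, fit.mu)

    trend = nbglm.fit_dispersion_trend(base_means, genewise)
    disp = nbglm.shrink_dispersion_map(counts, design, sf, mu_matrix,
                                       genewise, trend, base_means)

    lrt_df = (design.n_coef - reduced_design.n_coef
              if reduced_design is not None else 0)
    rows = np.full((n_genes, 6), np.nan)
    for g in range(n_genes):
        row = counts[g]
        rows[g, 0] = base_means[g]
        if np.all(row == 0):
            continue
        fit = nbglm.fit_glm_irls(row, design, sf, disp.map[g])
        out = nbglm.wald_test(fit, coef_name)
        if reduced_design is not None:
            red = nbglm.fit_glm_irls(row, reduced_design, sf, disp.map[g])
            lrt = nbglm.likelihood_ratio_test(fit, red, lrt_df)
            rows[g, 1:5] = (out.lfc, out.se, lrt.stat, lrt.pvalue)
        else:
            rows[g, 1:5] = (out.lfc, out.se, out.stat, out.pvalue)
    rows[:, 5] = nbglm.bh_adjust(rows[:, 4])
    return pd.DataFrame(rows, index=list(gene_ids), columns=RESULT_COLUMNS)


def run_interaction_model(exp: ValidatedExperiment, with_batch: bool = False,
                          contrast: tuple | None = None,
                          test: str = "wald") -> pd.DataFrame:
    """ΔTE via the interaction coefficient on the combined count matrix.

    ``test="wald"`` (default) tests the single interaction coefficient of
    the requested contrast; ``test="lrt"`` drops *all* interaction columns
    from the reduced design and tests them jointly by likelihood ratio,
    which is the appropriate global test when there are more than two
    condition levels (the reported LFC still belongs to the contrast).
    """
    if test not in ("wald", "lrt"):
        raise ValueError(f"unknown test {test!r}; use 'wald' or 'lrt'")
    samples = _combined_sample_table(exp)
    combined = exp.ribo.hstack(exp.rna).subset_samples(samples.sample_ids)
    ref, level = _resolve_contrast(samples, contrast)
    design = nbglm.build_design(samples, with_batch=with_batch,
                                with_interaction=True, condition_ref=ref)
    sf = compute_size_factors(combined)
    coef = nbglm.interaction_coef_name(level)
    reduced = None
    if test == "lrt":
        keep = [c for c in design.columns if ".SeqTypeRIBO" not in c]
        reduced = design.subset(keep)
    return fit_result_table(combined.counts, combined.gene_ids, design,
                            sf.to_numpy(), coef, reduced_design=reduced)


def run_assay_model(counts: CountMatrix, samples: SampleTable,
                    with_batch: bool = False,
                    contrast: tuple | None = None) -> pd.DataFrame:
    """Per-assay condition effect (ΔRNA or ΔRPF) with its own size factors."""
    if samples.data["condition"].nunique() < 2:
        raise nbglm.DesignError("a single condition level cannot be contrasted")
    counts = counts.subset_samples(samples.sample_ids)
    ref, level = _resolve_contrast(samples, contrast)
    design = nbglm.build_design(samples, with_batch=with_batch,
                                with_interaction=False, condition_ref=ref)
    sf = compute_size_factors(counts)
    coef = nbglm.condition_coef_name(level, ref)
    return fit_result_table(counts.counts, counts.gene_ids, design,
                            sf.to_numpy(), coef)


def run_delta_te(exp: ValidatedExperiment, with_batch: bool = False,
                 contrast: tuple | None = None, alpha: float = 0.05,
                 lfc_cutoff: float = 0.0, outdir=None,
                 make_figures: bool = True) -> DTEResult:
    """Full analysis: three fits, classification, and the Results/ layout.

    When ``outdir`` is given, writes fold_changes/{deltaTE,deltaRibo,
    deltaRNA}.txt, gene_lists/*.txt and (optionally) Results_figures.pdf.
    """
    te = run_interaction_model(exp, with_batch=with_batch, contrast=contrast)
    rna = run_assay_model(exp.rna, exp.samples.subset_seqtype("RNA"),
                          with_batch=with_batch, contrast=contrast)
    rpf = run_assay_model(exp.ribo, exp.samples.subset_seqtype("RIBO"),
                          with_batch=with_batch, contrast=contrast)
    samples = _combined_sample_table(exp)
    ref, level = _resolve_contrast(samples, contrast)
    result = DTEResult(te=te, rna=rna, rpf=rpf, contrast=(ref, level), alpha=alpha)
    result.classes, result.class_counts = _classify.classify_table(
        result, alpha=alpha, lfc_cutoff=lfc_cutoff)

    if outdir is not None:
        fc_dir = os.path.join(outdir, "fold_changes")
        os.makedirs(fc_dir, exist_ok=True)
        write_result_table(te, os.path.join(fc_dir, "deltaTE.txt"))
        write_result_table(rpf, os.path.join(fc_dir, "deltaRibo.txt"))
        write_result_table(rna, os.path.join(fc_dir, "deltaRNA.txt"))
        write_gene_lists(result.classes["class"],
                         os.path.join(outdir, "gene_lists"))
        if make_figures:
            from .interface import write_results_figures
            write_results_figures(exp, result,
                                  os.path.join(outdir, "Results_figures.pdf"))
    return result


def _combined_sample_table(exp: ValidatedExperiment) -> SampleTable:
    """Sample table reordered to ribo columns first, then rna columns."""
    order = list(exp.ribo.sample_ids) + list(exp.rna.sample_ids)
    df = exp.samples.data.set_index("sample_id").loc[order].reset_index()
    return SampleTable(df)


def _resolve_contrast(samples: SampleTable, contrast: tuple | None) -> tuple:
    levels = samples.conditions
    if contrast is None:
        if len(levels) < 2:
            raise nbglm.DesignError("need at least two condition levels")
        return levels[0], levels[1]
    ref, level = str(contrast[0]), str(contrast[1])
    for lv in (ref, level):
        if lv not in levels:
            raise nbglm.DesignError(
                f"condition level {lv!r} not present; available: {levels}")
    return ref, level
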