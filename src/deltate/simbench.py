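"""Count-level simulation of paired Ribo/RNA experiments and benchmarking.

The generator draws, per gene, a baseline mRNA abundance q_g ~ LogNormal and
a translation-efficiency multiplier kappa_g ~ LogNormal, then plants known
log2 effects (ΔRNA on transcription, ΔTE on translation efficiency) by
regulatory class:

* forwarded:        ΔRNA != 0, ΔTE = 0 (transcriptional change forwarded)
* exclusive:        ΔRNA = 0,  ΔTE != 0 (translation-only)
* intensified:      both nonzero, same sign
* buffered:         both nonzero, opposite sign
* buffered_special: ΔTE = -ΔRNA exactly (RPF mean unchanged)
* null (remainder): no effect

Expected counts are mean x library factor (x a batch multiplier for
batch-affected genes in the non-reference batch, in both assays) and counts
are drawn NB with a dispersion from the jittered trend a0 + a1/q. Each gene
uses its own deterministic RNG substream, so truth and counts for gene g do
not depend on n_genes.

The module also implements the two baseline DTEG callers used for
comparison: the Ratio method (z-score of the per-gene difference of
DE fold changes, |z| > 1.5) and the Overlap method (significant in exactly
one assay), plus confusion-matrix evaluation against the simulated truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dataio import CountMatrix, SampleTable


@dataclass
class SimConfig:
    """Simulation parameters; defaults give a realistic bulk experiment."""

    n_genes: int = 2000
    reps_per_cell: int = 4           # replicates per (condition, assay)
    frac_forwarded: float = 0.0
    frac_exclusive: float = 0.0
    frac_intensified: float = 0.0
    frac_buffered: float = 0.0
    frac_buffered_special: float = 0.0
    lfc_rna_range: tuple = (0.75, 2.0)   # |log2| magnitude, random sign
    lfc_te_range: tuple = (0.75, 2.0)
    base_mean_meanlog: float = float(np.log(250.0))
    base_mean_sdlog: float = 1.0
    te_multiplier_sdlog: float = 0.5
    disp_a0: float = 0.01
    disp_a1: float = 2.0
    disp_jitter_sdlog: float = 0.3
    libsize_range: tuple = (0.7, 1.3)
    n_batches: int = 1
    frac_batch_genes: float = 0.0
    batch_lfc_sd: float = 1.0
    base_mean_min: float = 0.0       # floor on q_g (0 disables)
    seed: int = 0

    def class_fractions(self) -> dict:
        return {
            "forwarded": self.frac_forwarded,
            "exclusive": self.frac_exclusive,
            "intensified": self.frac_intensified,
            "buffered": self.frac_buffered,
            "buffered_special": self.frac_buffered_special,
        }

    def validate(self) -> None:
        total = sum(self.class_fractions().values())
        if not 0.0 <= total <= 1.0 + 1e-12:
            raise ValueError(f"class fractions sum to {total}; must be <= 1")
        if any(f < 0 for f in self.class_fractions().values()):
            raise ValueError("class fractions must be non-negative")
        if self.n_genes < 1 or self.reps_per_cell < 2 or self.n_batches < 1:
            raise ValueError("need n_genes >= 1, reps_per_cell >= 2, n_batches >= 1")


def _gene_rng(seed: int, g: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                        spawn_key=(int(g),)))


def _assign_classes(cfg: SimConfig) -> list:
    """Deterministic class labels by index blocks; remainder is null."""
    labels = []
    for cls, frac in cfg.class_fractions().items():
        labels.extend([cls] * int(round(frac * cfg.n_genes)))
    labels = labels[: cfg.n_genes]
    labels.extend(["null"] * (cfg.n_genes - len(labels)))
    return labels


def _draw_magnitude(rng, rng_range) -> float:
    lo, hi = rng_range
    return float(rng.uniform(lo, hi)) * (1.0 if rng.random() < 0.5 else -1.0)


def simulate_dataset(cfg: SimConfig):
    """Generate (ribo CountMatrix, rna CountMatrix, SampleTable, SimTruth).

    SimTruth is a per-gene DataFrame with columns class, lfc_rna, lfc_te and
    batch_affected, indexed by gene id. Fully reproducible from cfg.seed.
    """
    cfg.validate()
    n = cfg.n_genes
    reps = cfg.reps_per_cell
    conditions = ["1", "2"]
    gene_ids = [f"gene{g:05d}" for g in range(n)]

    # samples: reps per (condition, seqtype); batches alternate within a cell
    # so batch is crossed with condition and seqtype (full-rank design)
    rows, ribo_ids, rna_ids = [], [], []
    for seq in ("RIBO", "RNA"):
        for cond in conditions:
            for r in range(reps):
                sid = f"{seq.lower()}_c{cond}_r{r + 1}"
                batch = str(r % cfg.n_batches + 1)
                row = {"sample_id": sid, "condition": cond, "seqtype": seq}
                if cfg.n_batches > 1:
                    row["batch"] = batch
                rows.append(row)
                (ribo_ids if seq == "RIBO" else rna_ids).append(sid)
    samples = SampleTable(pd.DataFrame(rows))
    sdf = samples.data

    lib_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(cfg.seed), spawn_key=(2**20,)))
    lib = lib_rng.uniform(*cfg.libsize_range, size=len(sdf))
    in_cond2 = (sdf["condition"] == "2").to_numpy()
    is_ribo = (sdf["seqtype"] == "RIBO").to_numpy()
    if cfg.n_batches > 1:
        batch_idx = sdf["batch"].astype(int).to_numpy() - 1
    else:
        batch_idx = np.zeros(len(sdf), dtype=int)

    labels = _assign_classes(cfg)
    counts = np.zeros((n, len(sdf)), dtype=np.int64)
    truth_rows = []
    for g in range(n):
        rng = _gene_rng(cfg.seed, g)
        q = float(rng.lognormal(cfg.base_mean_meanlog, cfg.base_mean_sdlog))
        q = max(q, cfg.base_mean_min)
        kappa = float(rng.lognormal(0.0, cfg.te_multiplier_sdlog))
        cls = labels[g]
        if cls == "forwarded":
            d_rna, d_te = _draw_magnitude(rng, cfg.lfc_rna_range), 0.0
        elif cls == "exclusive":
            d_rna, d_te = 0.0, _draw_magnitude(rng, cfg.lfc_te_range)
        elif cls == "intensified":
            d_rna = _draw_magnitude(rng, cfg.lfc_rna_range)
            d_te = float(np.sign(d_rna)) * float(
                rng.uniform(*cfg.lfc_te_range))
        elif cls == "buffered":
            d_rna = _draw_magnitude(rng, cfg.lfc_rna_range)
            d_te = -float(np.sign(d_rna)) * float(
                rng.uniform(*cfg.lfc_te_range))
        elif cls == "buffered_special":
            d_rna = _draw_magnitude(rng, cfg.lfc_rna_range)
            d_te = -d_rna
        else:
            d_rna, d_te = 0.0, 0.0

        batch_affected = (cfg.n_batches > 1 and cfg.frac_batch_genes > 0
                          and rng.random() < cfg.frac_batch_genes)
        b_lfc = (rng.normal(0.0, cfg.batch_lfc_sd) if batch_affected else 0.0)

        alpha = (cfg.disp_a0 + cfg.disp_a1 / q) * float(
            rng.lognormal(0.0, cfg.disp_jitter_sdlog))
        alpha = float(np.clip(alpha, 1e-8, 10.0))

        rna_mean = q * np.where(in_cond2, 2.0 ** d_rna, 1.0)
        te_mult = kappa * np.where(in_cond2, 2.0 ** d_te, 1.0)
        mean = np.where(is_ribo, rna_mean * te_mult, rna_mean)
        if batch_affected:
            mean = mean * np.where(batch_idx > 0, 2.0 ** b_lfc, 1.0)
        mu = np.clip(mean * lib, 1e-8, None)
        r = 1.0 / alpha
        counts[g] = rng.negative_binomial(r, r / (r + mu))
        truth_rows.append((cls, d_rna, d_te, bool(batch_affected)))

    truth = pd.DataFrame(truth_rows, index=gene_ids,
                         columns=["class", "lfc_rna", "lfc_te", "batch_affected"])
    ribo = CountMatrix(gene_ids, ribo_ids,
                       counts[:, is_ribo])
    rna = CountMatrix(gene_ids, rna_ids, counts[:, ~is_ribo])
    return ribo, rna, samples, truth


# ---------------------------------------------------------------------------
# baseline callers
# ---------------------------------------------------------------------------

def ratio_method_calls(rpf: pd.DataFrame, rna: pd.DataFrame,
                       z_cut: float = 1.5) -> pd.Series:
    """Ratio-method DTEG calls: z-score of d = ΔRPF - ΔRNA over genes.

    d_g is standardised by the mean and SD over all genes tested in both
    assays; genes with |z| above the cutoff (default 1.5) are called.
    """
    d = rpf["log2FoldChange"] - rna["log2FoldChange"]
    tested = d.notna()
    calls = pd.Series(False, index=d.index)
    sd = d[tested].std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        warnings.warn("zero spread in ΔRPF - ΔRNA; ratio method makes no calls",
                      UserWarning, stacklevel=2)
        return calls
    z = (d[tested] - d[tested].mean()) / sd
    calls.loc[tested] = (z.abs() > z_cut).to_numpy()
    return calls


def overlap_method_calls(rpf: pd.DataFrame, rna: pd.DataFrame,
                         alpha: float = 0.05) -> pd.Series:
    """Overlap-method calls: significant in exactly one of the two assays."""
    rpf_sig = (rpf["padj"] < alpha).fillna(False)
    rna_sig = (rna["padj"] < alpha).fillna(False)
    return rpf_sig ^ rna_sig


def dte_method_calls(te: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """ΔTE calls: significant interaction coefficient."""
    return (te["padj"] < alpha).fillna(False)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_calls(calls: pd.Series, truth: pd.DataFrame) -> dict:
    """Confusion-matrix rates of a boolean call vector against the truth.

    A gene is a true positive target iff its true ΔTE is nonzero (all
    translationally regulated genes form the positive set).
    """
    calls = calls.reindex(truth.index).fillna(False).astype(bool)
    positive = truth["lfc_te"] != 0.0
    tp = int((calls & positive).sum())
    fp = int((calls & ~positive).sum())
    fn = int((~calls & positive).sum())
    tn = int((~calls & ~positive).sum())
    n_pos, n_neg = tp + fn, fp + tn
    return {
        "TP": tp, "FP": fp, "FN": fn, "TN": tn,
        "TPR": tp / n_pos if n_pos else np.nan,
        "FPR": fp / n_neg if n_neg else np.nan,
        "precision": tp / (tp + fp) if (tp + fp) else np.nan,
        "accuracy": (tp + tn) / len(truth),
    }


def accuracy_curve(call_fn, thresholds, truth: pd.DataFrame) -> pd.DataFrame:
    """Sweep a caller over thresholds; returns per-threshold rates + AUC.

    ``call_fn(threshold)`` must return a boolean Series aligned with truth.
    The AUC column holds the trapezoidal area under the accuracy curve over
    the threshold sweep, normalised by the threshold span.
    """
    recs = []
    for t in thresholds:
        m = evaluate_calls(call_fn(t), truth)
        m["threshold"] = t
        recs.append(m)
    frame = pd.DataFrame(recs).set_index("threshold")
    ts = np.asarray(list(thresholds), dtype=float)
    span = ts.max() - ts.min()
    if len(ts) > 1 and span > 0:
        auc = float(np.trapezoid(frame["accuracy"].to_numpy(), ts)) / span
    else:
        auc = float(frame["accuracy"].iloc[0])
    frame.attrs["accuracy_auc"] = auc
    return frame


def run_benchmark(cfg: SimConfig, alpha: float = 0.05,
                  thresholds=(0.01, 0.05, 0.1)) -> pd.DataFrame:
    """Simulate one dataset and compare the four DTEG callers.

    ΔTE is run with and without the batch covariate; the Ratio and Overlap
    baselines use per-assay fits without batch correction, matching the
    published forms of those methods. Returns one row of rates per method
    at padj < alpha (|z| > 1.5 for the ratio method) plus the accuracy AUC
    over the threshold sweep where a threshold applies.
    """
    from .dataio import validate_experiment
    from .dte import run_assay_model, run_interaction_model

    ribo, rna, samples, truth = simulate_dataset(cfg)
    exp = validate_experiment(ribo, rna, samples)

    te_plain = run_interaction_model(exp, with_batch=False)
    rna_res = run_assay_model(exp.rna, samples.subset_seqtype("RNA"),
                              with_batch=False)
    rpf_res = run_assay_model(exp.ribo, samples.subset_seqtype("RIBO"),
                              with_batch=False)
    methods = {
        "dte": (lambda a: dte_method_calls(te_plain, a), True),
        "ratio": (lambda z: ratio_method_calls(rpf_res, rna_res, z), False),
        "overlap": (lambda a: overlap_method_calls(rpf_res, rna_res, a), True),
    }
    if cfg.n_batches > 1:
        te_batch = run_interaction_model(exp, with_batch=True)
        methods["dte_batch"] = (lambda a: dte_method_calls(te_batch, a), True)

    rows = {}
    for name, (fn, is_fdr) in methods.items():
        cut = alpha if is_fdr else 1.5
        metrics = evaluate_calls(fn(cut), truth)
        sweep = list(thresholds) if is_fdr else [1.0, 1.5, 2.0]
        curve = accuracy_curve(fn, sweep, truth)
        metrics["accuracy_auc"] = curve.attrs["accuracy_auc"]
        rows[name] = metrics
    out = pd.DataFrame(rows).T
    out.attrs["config"] = asdict(cfg)
    return out
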