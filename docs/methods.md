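# Methods

## The model

Ribosome profiling (Ribo-seq) counts ribosome-protected fragments (RPFs)
per gene; paired RNA-seq counts the underlying mRNA. A gene's translation
efficiency (TE) is the ratio of its normalised RPF level to its normalised
mRNA level, and translational regulation shows up as a change in TE between
conditions (ΔTE) that cannot be explained by the transcriptional change
alone.

`deltate` models the raw counts K_gj of gene g in sample j as negative
binomial, K_gj ~ NB(mean = s_j · q_gj, dispersion = α_g), with
Var = μ + α μ², and

    log q_gj = β0 + β1·c_j + β2·r_j + β3·(c_j · r_j)

where c_j indicates the non-reference condition and r_j indicates Ribo-seq
(RNA-seq is always the sequencing-type reference). Writing out the four
cell means shows that β1 is the transcriptional change (ΔRNA), β1 + β3 the
RPF change (ΔRPF), and the interaction coefficient

    β3 = ΔRPF − ΔRNA = log TE(condition 2) − log TE(condition 1) = ΔTE

so a Wald test of β3 = 0 is a direct test for differential translation
efficiency. Known batches enter as additive indicator terms
(`~ Batch + Condition + SeqType + Condition:SeqType`); a batch that is a
function of condition makes the design rank-deficient and is rejected at
validation. With more than two conditions each non-reference level gets its
own condition and interaction column and contrasts are taken pairwise
against the reference; a likelihood-ratio test across nested designs is
available for joint tests.

Genes are then classified from the three BH-adjusted test families
(ΔTE from the combined model; ΔRNA and ΔRPF from per-assay
`~ [Batch +] Condition` models):

| class            | ΔRPF | ΔRNA | ΔTE | extra rule                    |
|------------------|------|------|-----|-------------------------------|
| no change        | n.s. | n.s. | n.s.|                               |
| forwarded        | sig  | sig  | n.s.|                               |
| exclusive        | sig  | n.s. | sig |                               |
| intensified      | sig  | sig  | sig | sign(ΔTE)·sign(ΔRNA) > 0      |
| buffered         | sig  | sig  | sig | sign(ΔTE)·sign(ΔRNA) < 0      |
| buffered (special)| n.s.| sig  | sig | TE cancels the RNA change     |
| undetermined     | any other pattern with ≥ 1 significant call |

Special-case buffered genes appear in the buffered gene list but keep their
own label in memory. A missing adjusted p-value counts as not significant
and tags the gene (`has_NA`).

## Estimation pipeline

1. **Size factors** — median-of-ratios over genes with all-positive counts.
   For the interaction model the factors are computed jointly on the
   column-concatenated [ribo | rna] matrix, mirroring the combined design;
   the per-assay models recompute factors within their own assay. No
   rescaling to unit geometric mean is applied, so outputs are bit-for-bit
   reproducible from the definition.
2. **GLM fit** — IRLS on the natural-log scale with offsets log s_j,
   a ridge of 1e-6 on non-intercept coefficients for stability, and
   convergence at max |Δβ| < 1e-8 (≤ 100 iterations). After convergence up
   to 20 unridged Newton steps polish the solution so well-posed fits reach
   the exact MLE (the ridge alone leaves a ~1e-6 bias on saturated
   designs); if the unpenalised steps diverge the ridged estimate is kept.
   Coefficients and standard errors are reported in log2. All-zero genes
   are not fitted and propagate NA through to the output tables.
3. **Dispersion** — per gene: a method-of-moments initial value
   ((v − m)/m², floored), an IRLS fit at that value, then maximisation of
   the Cox-Reid-adjusted profile likelihood
   ℓ(α) − ½ log det(XᵀWX) over log α ∈ [log 1e-8, log 10] (coarse scan +
   bounded Brent; fully deterministic). Across genes a parametric trend
   α_tr(μ) = a0 + a1/μ is fitted by Gamma-family scoring iterations on
   1/μ, iteratively excluding genes whose ratio to the trend leaves
   [1e-4, 15]; with fewer than 50 usable genes the trend degenerates to
   the median dispersion. Finally each gene's dispersion is re-estimated
   as the MAP under a normal prior on log α centred at the trend, with
   prior variance max(var(log residuals) − trigamma((n−p)/2), 0.25).
   Genes whose log residual exceeds 2 SD above the trend are dispersion
   outliers and keep their gene-wise estimate.
4. **Testing** — Wald test of the requested coefficient at the MAP
   dispersion; Benjamini-Hochberg step-up within each of the three result
   families separately (three independent model runs); NA p-values are
   excluded from the BH denominator.

Deliberate simplifications relative to the reference differential-
expression engine this design is modelled on: no Cook's-distance outlier
replacement, no independent filtering (BH is applied to all tested genes),
and no posterior shrinkage of fold changes — classification uses the signs
of the unshrunk MLE estimates. Shrinkage would alter LFC magnitudes but
not p-values, so class membership by significance is unaffected. These
choices favour determinism and auditability; numeric parity with engines
that implement those refinements is therefore approximate rather than
bit-exact.

## Synthetic data

`simbench.simulate_dataset` emulates a paired bulk experiment at the count
level. Per gene: baseline mRNA abundance q ~ LogNormal(log 250, 1), TE
multiplier κ ~ LogNormal(0, 0.5), dispersion (0.01 + 2/q) with LogNormal
(sd 0.3) jitter; per sample a library factor ~ Uniform(0.7, 1.3). Effects
are planted by regulatory class with |log2| magnitudes ~ Uniform(0.75, 2)
and random sign (condition-2 RNA mean q·2^ΔRNA, Ribo mean
q·κ·2^(ΔRNA+ΔTE)). Batch-affected genes receive an extra 2^b multiplier
(b ~ Normal(0, sd)) in the non-reference batch in both assays; batches are
crossed with condition and assay so designs stay full-rank. Every gene has
its own deterministic RNG substream derived from (seed, gene index), so
enlarging the panel never reshuffles earlier genes.

What the generator does *not* emulate: read-level artefacts (alignment,
multimapping, 3-nt periodicity), correlated counts between the paired
assays beyond the shared mean structure, gene-length effects, and
heavy-tailed outlier samples. Passing tests therefore demonstrate the
statistical machinery under the stated NB assumptions, not robustness to
every artefact of real libraries.

## Benchmark

The benchmark compares four DTEG callers on one simulated dataset, with
true positives defined as genes with true ΔTE ≠ 0:

* **ΔTE (with/without batch)** — significant interaction coefficient at
  padj < 0.05;
* **Ratio method** — z-score of d_g = ΔRPF_g − ΔRNA_g standardised over
  all tested genes, called at |z| > 1.5;
* **Overlap method** — significant in exactly one of the two per-assay
  analyses.

The baselines run on per-assay fits without a batch covariate, matching
their published forms. The default benchmark condition uses 2000 genes,
4 replicates per condition per assay, a full regulatory mixture
(10% forwarded, 10% exclusive, 5% intensified, 5% buffered, 2% special-
case buffered, |ΔTE| = 1 where nonzero), 2 batches affecting 30% of genes
with batch log2-effect SD 1. The mixture matters: with exclusive-only
truth the overlap caller degenerates to a plain single-assay test and its
documented failure modes (false calls on transcriptionally forwarded
genes, inability to call genes significant in both assays) cannot appear.
The z-standardisation of the ratio method is this package's reading of
that heuristic — the original publications give no formula — and is
documented as such.

Accuracy is reported at the working threshold and as a trapezoidal AUC
over a small threshold sweep (0.01/0.05/0.1 for FDR-based callers;
1/1.5/2 for the z cutoff), normalised by the sweep span.

## Numerical and design choices

* Dispersion bounds [1e-8, 10]; all 1-D optimisation on the log scale with
  deterministic bracketing — there is no randomness anywhere in fitting.
* PCA (QC diagnostic) uses log2(normalised counts + 1) on the 500
  most-variable genes, gene-centred, via SVD; variance fractions are over
  all components and sum to 1. A variance-stabilising transform would be
  an alternative; the simple log transform keeps the diagnostic
  dependency-free and deterministic.
* Sample-table parsing is case-insensitive for SeqType (stored RIBO/RNA);
  a hard floor of 2 replicates per (condition, seqtype) cell is enforced
  (dispersion estimation is impossible below), with a warning below 3.
* Gene-set mismatches between assays are an error by default; a lenient
  flag intersects with a warning naming the dropped ids.
* The "save state" CLI flag writes a portable JSON summary of the run
  rather than a language-specific binary.
* Problem sizes in tests and in the acceptance script (2000-gene
  simulations, 50-gene optimizer audits) are chosen to exercise the full
  pipeline at desk scale while keeping a complete run in minutes on one
  core.

## Known limitations

* Wald tests at MAP dispersions can be mildly anticonservative below
  3 replicates per cell; the null-calibration test pins the behaviour at
  n = 3.
* Only categorical covariates are supported (no continuous confounders,
  no time-course splines); no zero-inflation; no isoform- or uORF-level
  resolution.
* The ratio-method baseline's z-score construction is under-specified in
  the literature; conclusions about that baseline are conditional on the
  standardisation defined above.
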