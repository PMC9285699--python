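"""Negative-binomial GLM core.

Gene-wise counts K_gj are modelled as NB(mu_gj, alpha_g) with
var = mu + alpha*mu^2 and log mu_gj = log s_j + x_j . beta_g, where s_j is
the sample size factor and x_j the row of a treatment-coded design matrix.
For the paired Ribo/RNA design ~ Condition + SeqType + Condition:SeqType the
interaction coefficient is exactly the log fold change in translation
efficiency between conditions, which is what this package tests.

Fitting is IRLS on the natural-log scale with a tiny ridge on non-intercept
coefficients; coefficients and standard errors are reported in log2 units.
Dispersion is estimated per gene by a Cox-Reid-adjusted profile likelihood,
regularised by empirical-Bayes shrinkage toward a parametric mean-dispersion
trend alpha_tr(mu) = a0 + a1/mu.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, polygamma
from scipy.stats import chi2, norm

from .dataio import SampleTable

LOG2 = np.log(2.0)
ALPHA_MIN = 1e-8
ALPHA_MAX = 10.0
RIDGE = 1e-6
IRLS_TOL = 1e-8
IRLS_MAXITER = 100


class DesignError(ValueError):
    pass


@dataclass
class DesignMatrix:
    """Treatment-coded 0/1 design with named coefficients."""

    columns: list
    values: np.ndarray
    reference_levels: dict

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.columns):
            raise DesignError("column count does not match coefficient names")
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise DesignError(
                "non-full-rank design (a covariate is confounded with another); "
                f"columns: {self.columns}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_coef(self) -> int:
        return self.values.shape[1]

    def column_index(self, name: str) -> int:
        try:
            return self.columns.index(name)
        except ValueError:
            raise DesignError(
                f"unknown coefficient {name!r}; available: {self.columns}"
            ) from None

    def subset(self, names) -> "DesignMatrix":
        """Reduced design keeping the named columns (for LRT nesting)."""
        idx = [self.column_index(n) for n in names]
        return DesignMatrix(list(names), self.values[:, idx], dict(self.reference_levels))


def build_design(samples: SampleTable, with_batch: bool = False,
                 with_interaction: bool = True,
                 condition_ref: str | None = None) -> DesignMatrix:
    """Build the model design from a sample table.

    Column order: intercept, batch indicators, condition indicators, the
    RIBO indicator, then one interaction column per non-reference condition.
    The sequencing-type reference level is always RNA so the interaction
    coefficient reads as (Ribo change) - (RNA change). Interaction columns
    are named in the ``Condition<level>.SeqTypeRIBO`` style.
    """
    df = samples.data
    cond_levels = sorted(df["condition"].unique())
    if condition_ref is None:
        condition_ref = cond_levels[0]
    if condition_ref not in cond_levels:
        raise DesignError(f"condition reference level {condition_ref!r} not present")
    cond_nonref = [c for c in cond_levels if c != condition_ref]

    cols, names = [np.ones(len(df))], ["Intercept"]
    refs = {"condition": condition_ref, "seqtype": "RNA"}

    if with_batch:
        if "batch" not in df.columns:
            raise DesignError("batch covariate requested but no batch column present")
        batch_levels = sorted(df["batch"].unique())
        refs["batch"] = batch_levels[0]
        for b in batch_levels[1:]:
            cols.append((df["batch"] == b).to_numpy(float))
            names.append(f"Batch_{b}_vs_{batch_levels[0]}")

    for c in cond_nonref:
        cols.append((df["condition"] == c).to_numpy(float))
        names.append(f"Condition_{c}_vs_{condition_ref}")

    both_seqtypes = df["seqtype"].nunique() == 2
    if both_seqtypes:
        ribo = (df["seqtype"] == "RIBO").to_numpy(float)
        cols.append(ribo)
        names.append("SeqType_RIBO_vs_RNA")
        if with_interaction:
            for c in cond_nonref:
                cols.append((df["condition"] == c).to_numpy(float) * ribo)
                names.append(f"Condition{c}.SeqTypeRIBO")

    return DesignMatrix(names, np.column_stack(cols), refs)


def interaction_coef_name(level: str) -> str:
    return f"Condition{level}.SeqTypeRIBO"


def condition_coef_name(level: str, ref: str) -> str:
    return f"Condition_{level}_vs_{ref}"


# ---------------------------------------------------------------------------
# likelihood and fitting
# ---------------------------------------------------------------------------

@dataclass
class GeneFit:
    """Per-gene GLM fit: coefficients in log2, SEs in log2, fitted means."""

    beta: np.ndarray
    se: np.ndarray
    mu: np.ndarray
    loglik: float
    converged: bool
    base_mean: float
    columns: list = field(default_factory=list)


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB log-likelihood with var = mu + alpha*mu^2 (alpha > 0 enforced)."""
    alpha = max(float(alpha), ALPHA_MIN)
    r = 1.0 / alpha
    mu = np.clip(mu, 1e-12, None)
    return float(np.sum(
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
    ))


def moments_dispersion(counts_row: np.ndarray, sf) -> float:
    """Method-of-moments dispersion of normalised counts, floored at 1e-8.

    alpha0 = (v - m) / m^2 collapses to the floor in the Poisson limit
    (v <= m). All-zero rows return NaN: they carry no information.
    """
    sf = np.asarray(sf, dtype=float)
    yn = np.asarray(counts_row, dtype=float) / sf
    if yn.size < 2 or np.all(yn == 0):
        return np.nan
    m = yn.mean()
    v = yn.var(ddof=1)
    return float(min(max((v - m) / m**2, ALPHA_MIN), ALPHA_MAX))


def fit_glm_irls(counts_row: np.ndarray, design: DesignMatrix, sf,
                 alpha: float, ridge: float = RIDGE, tol: float = IRLS_TOL,
                 maxiter: int = IRLS_MAXITER) -> GeneFit:
    """Fit one gene's NB GLM by iteratively reweighted least squares.

    The dispersion ``alpha`` is held fixed. A ridge penalty of ``ridge`` on
    the non-intercept coefficients stabilises separated designs; it is small
    enough to leave well-conditioned fits unchanged to ~1e-6. Non-convergence
    sets the flag rather than raising.
    """
    y = np.asarray(counts_row, dtype=float)
    X = design.values
    sf = np.asarray(sf, dtype=float)
    n, p = X.shape
    base_mean = float(np.mean(y / sf))
    if np.all(y == 0):
        nan = np.full(p, np.nan)
        return GeneFit(nan, nan.copy(), np.zeros(n), np.nan, False, 0.0,
                       list(design.columns))
    alpha = float(np.clip(alpha, ALPHA_MIN, ALPHA_MAX))
    offset = np.log(sf)

    # initial beta from least squares on the log scale
    z0 = np.log((y + 0.5) / sf)
    beta, *_ = np.linalg.lstsq(X, z0, rcond=None)
    R = np.diag(np.r_[0.0, np.full(p - 1, ridge)]) if p > 1 else np.zeros((1, 1))

    def irls_loop(beta, ridge_matrix, niter):
        ok = False
        for _ in range(niter):
            eta = np.clip(X @ beta, -30.0, 30.0)
            mu = np.exp(eta + offset)
            w = mu / (1.0 + alpha * mu)
            z = eta + (y - mu) / mu
            XtW = X.T * w
            try:
                beta_new = np.linalg.solve(XtW @ X + ridge_matrix, XtW @ z)
            except np.linalg.LinAlgError:
                break
            step = np.max(np.abs(beta_new - beta))
            if not np.all(np.isfinite(beta_new)):
                break
            beta = beta_new
            if step < tol:
                ok = True
                break
        return beta, ok

    beta, converged = irls_loop(beta, R, maxiter)
    if converged and p > 1:
        # polish without the ridge so well-posed fits reach the exact MLE;
        # fall back to the ridged estimate if the unpenalised steps diverge
        beta_polish, ok = irls_loop(beta.copy(), np.zeros((p, p)), 20)
        if ok and np.all(np.isfinite(beta_polish)):
            beta = beta_polish
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = np.exp(eta + offset)
    w = mu / (1.0 + alpha * mu)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return GeneFit(beta / LOG2, se / LOG2, mu, nb_loglik(y, mu, alpha),
                   converged, base_mean, list(design.columns))


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def cox_reid_loglik(alpha: float, y: np.ndarray, X: np.ndarray,
                    mu: np.ndarray) -> float:
    """Profile log-likelihood with the Cox-Reid adjustment -0.5*logdet(X'WX)."""
    alpha = max(float(alpha), ALPHA_MIN)
    w = mu / (1.0 + alpha * mu)
    A = (X.T * w) @ X
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf
    return nb_loglik(y, mu, alpha) - 0.5 * logdet


def _maximize_log_alpha(objective, n_coarse: int = 50) -> tuple[float, bool]:
    """Deterministic 1-D maximisation over log alpha in the allowed range.

    A coarse log-spaced scan brackets the optimum, then bounded Brent
    refinement runs inside the bracketing interval. Returns (alpha, at_bound).
    """
    lo, hi = np.log(ALPHA_MIN), np.log(ALPHA_MAX)
    grid = np.linspace(lo, hi, n_coarse)
    vals = np.array([objective(g) for g in grid])
    k = int(np.argmax(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, n_coarse - 1)]
    res = minimize_scalar(lambda la: -objective(la), bounds=(a, b),
                          method="bounded", options={"xatol": 1e-10})
    log_alpha = float(res.x)
    if objective(log_alpha) < vals[k]:
        log_alpha = float(grid[k])
    at_bound = log_alpha <= lo + 1e-6 or log_alpha >= hi - 1e-6
    return float(np.exp(log_alpha)), at_bound


def profile_dispersion_mle(counts_row: np.ndarray, design: DesignMatrix, sf,
                           mu_init: np.ndarray) -> tuple[float, bool]:
    """Gene-wise dispersion MLE from the Cox-Reid-adjusted profile likelihood.

    The fitted means ``mu_init`` from an initial IRLS fit are held fixed while
    alpha is optimised on the log scale over [1e-8, 10]. Returns
    (alpha_hat, at_bound_flag).
    """
    y = np.asarray(counts_row, dtype=float)
    X = design.values
    mu = np.clip(np.asarray(mu_init, dtype=float), 1e-12, None)
    return _maximize_log_alpha(lambda la: cox_reid_loglik(np.exp(la), y, X, mu))


def fit_dispersion_trend(base_means: np.ndarray, genewise: np.ndarray,
                         min_genes: int = 50) -> tuple[float, float]:
    """Fit the parametric trend alpha_tr(mu) = a0 + a1/mu.

    Gamma-family regression of the gene-wise dispersions on 1/mu (identity
    link, scoring iterations), iteratively excluding genes whose ratio to the
    current trend falls outside [1e-4, 15]. With fewer than ``min_genes``
    usable genes the trend degenerates to the median dispersion (a1 = 0).
    """
    mu = np.asarray(base_means, dtype=float)
    d = np.asarray(genewise, dtype=float)
    usable = np.isfinite(d) & np.isfinite(mu) & (mu > 0) & (d > 10 * ALPHA_MIN)
    if usable.sum() < min_genes:
        warnings.warn(
            f"only {int(usable.sum())} usable genes for the dispersion trend; "
            "falling back to a flat median trend", UserWarning, stacklevel=2,
        )
        med = float(np.median(d[np.isfinite(d)])) if np.isfinite(d).any() else 0.1
        return max(med, ALPHA_MIN), 0.0

    def gamma_identity_fit(dd, mm):
        # scoring iterations for a Gamma GLM with identity link
        Z = np.column_stack([np.ones_like(mm), 1.0 / mm])
        theta = np.array([max(np.median(dd), 1e-6), 1.0])
        for _ in range(100):
            pred = np.clip(Z @ theta, 1e-10, None)
            w = 1.0 / pred**2
            ZtW = Z.T * w
            try:
                theta_new = np.linalg.solve(ZtW @ Z, ZtW @ dd)
            except np.linalg.LinAlgError:
                break
            theta_new = np.maximum(theta_new, 0.0)
            if np.max(np.abs(theta_new - theta)) < 1e-10:
                theta = theta_new
                break
            theta = theta_new
        return theta

    keep = usable.copy()
    a0, a1 = gamma_identity_fit(d[keep], mu[keep])
    for _ in range(10):
        pred = np.clip(a0 + a1 / mu, 1e-12, None)
        ratio = np.where(usable, d / pred, np.nan)
        new_keep = usable & (ratio > 1e-4) & (ratio < 15)
        if new_keep.sum() < min_genes or np.array_equal(new_keep, keep):
            break
        keep = new_keep
        a0, a1 = gamma_identity_fit(d[keep], mu[keep])
    if a0 <= 0 and a1 <= 0:
        return max(float(np.median(d[usable])), ALPHA_MIN), 0.0
    return float(a0), float(a1)


@dataclass
class DispersionModel:
    """Gene-wise, trend and final (MAP) dispersions plus outlier flags."""

    genewise: np.ndarray
    trend_params: tuple
    map: np.ndarray
    prior_sd: float
    outlier: np.ndarray

    def trend_at(self, mu) -> np.ndarray:
        a0, a1 = self.trend_params
        return a0 + a1 / np.clip(np.asarray(mu, dtype=float), 1e-12, None)


def shrink_dispersion_map(counts: np.ndarray, design: DesignMatrix, sf,
                          mu_matrix: np.ndarray, genewise: np.ndarray,
                          trend_params: tuple, base_means: np.ndarray
                          ) -> DispersionModel:
    """Empirical-Bayes shrinkage of gene-wise dispersions toward the trend.

    The final per-gene dispersion maximises the Cox-Reid profile likelihood
    plus a normal prior on log alpha centred at the trend value. The prior
    variance is the spread of log residuals around the trend minus the
    expected sampling variance trigamma((n - p)/2), floored at 0.25. Genes
    whose log residual exceeds 2 standard deviations above the trend are
    dispersion outliers and keep their gene-wise estimate.
    """
    X = design.values
    n, p = X.shape
    sf = np.asarray(sf, dtype=float)
    a0, a1 = trend_params
    mu_bar = np.clip(np.asarray(base_means, dtype=float), 1e-12, None)
    trend = a0 + a1 / mu_bar
    trend = np.clip(trend, ALPHA_MIN, ALPHA_MAX)

    with np.errstate(divide="ignore", invalid="ignore"):
        log_resid = np.log(genewise) - np.log(trend)
    ok = np.isfinite(log_resid) & (genewise > 10 * ALPHA_MIN)
    if ok.sum() >= 2:
        s2 = float(np.var(log_resid[ok], ddof=1))
    else:
        s2 = 1.0
    sd_resid = np.sqrt(s2)
    sampling_var = float(polygamma(1, max(n - p, 1) / 2.0))
    prior_var = max(s2 - sampling_var, 0.25)
    prior_sd = np.sqrt(prior_var)

    n_genes = counts.shape[0]
    final = np.empty(n_genes)
    outlier = np.zeros(n_genes, dtype=bool)
    for g in range(n_genes):
        if not np.isfinite(genewise[g]):
            final[g] = trend[g]
            continue
        if np.isfinite(log_resid[g]) and log_resid[g] > 2.0 * sd_resid:
            outlier[g] = True
            final[g] = genewise[g]
            continue
        y = counts[g].astype(float)
        mu = np.clip(mu_matrix[g], 1e-12, None)
        log_tr = np.log(trend[g])

        def objective(la, y=y, mu=mu, log_tr=log_tr):
            return (cox_reid_loglik(np.exp(la), y, X, mu)
                    - (la - log_tr) ** 2 / (2.0 * prior_var))

        final[g], _ = _maximize_log_alpha(objective)
    return DispersionModel(np.asarray(genewise, dtype=float), (a0, a1),
                           final, float(prior_sd), outlier)


# ---------------------------------------------------------------------------
# tests and multiple-testing adjustment
# ---------------------------------------------------------------------------

@dataclass
class TestOutcome:
    lfc: float
    se: float
    stat: float
    pvalue: float
    padj: float = np.nan


def wald_test(fit: GeneFit, coef_name: str) -> TestOutcome:
    """Two-sided Wald test of a single coefficient against zero."""
    try:
        idx = fit.columns.index(coef_name)
    except ValueError:
        raise DesignError(
            f"unknown coefficient {coef_name!r}; available: {fit.columns}"
        ) from None
    lfc, se = float(fit.beta[idx]), float(fit.se[idx])
    if not (np.isfinite(lfc) and np.isfinite(se)) or se <= 0:
        return TestOutcome(lfc, se, np.nan, np.nan)
    stat = lfc / se
    pvalue = 2.0 * norm.sf(abs(stat))
    return TestOutcome(lfc, se, stat, float(pvalue))


def likelihood_ratio_test(full: GeneFit, reduced: GeneFit, df: int) -> TestOutcome:
    """Chi-square LRT of nested NB GLMs sharing one dispersion."""
    if not set(reduced.columns) <= set(full.columns):
        raise DesignError("reduced model is not nested in the full model")
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    pvalue = float(chi2.sf(stat, df))
    return TestOutcome(np.nan, np.nan, stat, pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries are passed through
    and excluded from the denominator."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = int(mask.sum())
    if m == 0:
        return out
    pv = p[mask]
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[mask] = restored
    return out
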