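"""Negative-binomial differential expression on count matrices.

The model is the standard RNA-seq workhorse: per-gene counts are NB with
mean mu_gj = s_j * q_gj and variance mu + alpha * mu^2, where s_j is a
median-of-ratios size factor and alpha a per-gene dispersion.  A log-link
GLM with the sample condition (and optionally batch) as covariates is fit
by iteratively reweighted least squares, and the condition coefficient is
tested with a two-sided Wald test.  P-values are FDR-adjusted by the
Benjamini-Hochberg step-up.

This is a deliberately plain estimator: no empirical-Bayes dispersion
shrinkage, no outlier filtering, no fold-change shrinkage.  Downstream
stages only need (base_mean, log2fc, padj) semantics.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .experiment import CountExperiment

__all__ = [
    "size_factors",
    "estimate_dispersion",
    "nb_wald_test",
    "bh_adjust",
    "call_dats",
]

log = logging.getLogger(__name__)

_LN2 = np.log(2.0)
#: dispersion used inside the GLM is never below this, so IRLS weights
#: stay finite even for genes whose moment estimate hits zero
_MIN_ALPHA = 1e-8
_MAX_ITER = 100
_TOL = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors.

    factor_j = median over genes g (restricted to genes with a positive
    geometric mean, i.e. no zero count) of count_gj / geomean_g.  Two
    identical columns get equal factors; multiplying one column by a
    constant multiplies its factor by exactly that constant.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.size == 0 or mat.sum() == 0:
        raise ValueError("no usable genes: count matrix is empty or all zero")
    with np.errstate(divide="ignore"):
        logmat = np.log(mat)
    log_geomean = logmat.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError("no usable genes: every gene contains a zero count")
    log_ratios = logmat[usable] - log_geomean[usable, None]
    log_sf = np.median(log_ratios, axis=0)
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    factors: pd.Series,
    conditions: Sequence[str],
) -> pd.Series:
    """Per-gene method-of-moments NB dispersion on normalized counts.

    Within each condition that has >=2 replicates the sample variance is
    pooled (df-weighted); alpha_hat = max(0, (s2 - mean) / mean^2) with the
    grand mean of normalized counts.  Genes whose variance does not exceed
    the mean get alpha_hat = 0.
    """
    conditions = np.asarray(conditions)
    norm = counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    groups = [norm[:, conditions == c] for c in np.unique(conditions)]
    dfs = [g.shape[1] - 1 for g in groups]
    if sum(df for df in dfs if df > 0) == 0:
        raise ValueError("dispersion not estimable: no condition has >=2 replicates")
    ss = np.zeros(norm.shape[0])
    total_df = 0
    for g, df in zip(groups, dfs):
        if df > 0:
            ss += g.var(axis=1, ddof=1) * df
            total_df += df
    s2 = ss / total_df
    mean = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mean) / mean**2
    alpha = np.where(mean > 0, np.maximum(alpha, 0.0), 0.0)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _irls_nb(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fit an NB GLM with log link and fixed dispersion.

    Returns (beta, se, converged).
    """
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(np.mean(y / np.exp(offset)), 1e-8))
    for _ in range(_MAX_ITER):
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        xtw = X.T * w
        try:
            new_beta = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError:
            return beta, np.full(p, np.nan), False
        delta = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if not np.isfinite(beta).all():
            return np.zeros(p), np.full(p, np.nan), False
        if delta < _TOL:
            eta = np.clip(X @ beta + offset, -30.0, 30.0)
            mu = np.exp(eta)
            w = mu / (1.0 + alpha * mu)
            cov = np.linalg.inv((X.T * w) @ X)
            return beta, np.sqrt(np.diag(cov)), True
    return beta, np.full(p, np.nan), False


def _design_matrix(
    samples: pd.DataFrame, contrast: tuple[str, str], batch_covariate: bool
) -> tuple[np.ndarray, int]:
    """Intercept + indicator of the test condition (+ batch dummies).

    Returns the design and the column index of the condition coefficient.
    """
    test, _reference = contrast
    cond = (samples["condition"] == test).to_numpy(dtype=float)
    columns = [np.ones(len(samples)), cond]
    if batch_covariate and "batch" in samples.columns:
        levels = sorted(samples["batch"].astype(str).unique())
        for level in levels[1:]:
            columns.append((samples["batch"].astype(str) == level).to_numpy(dtype=float))
    return np.column_stack(columns), 1


def nb_wald_test(
    experiment: CountExperiment,
    contrast: tuple[str, str] = ("resistant", "sensitive"),
    batch_covariate: bool = False,
    dispersion: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of ``contrast = (test, reference)``.

    Returns a DE table with columns gene_id, base_mean, log2fc, se,
    wald_stat, pvalue, padj, converged.  All-zero genes get log2fc 0 and
    p 1; genes whose IRLS fit fails to converge are flagged and also get
    p 1 rather than aborting the run.
    """
    test, reference = contrast
    present = set(experiment.samples["condition"])
    if test not in present or reference not in present:
        raise ValueError(f"contrast conditions {contrast} not both present")
    mask = experiment.samples["condition"].isin([test, reference])
    exp = experiment.subset_samples(mask)
    counts = exp.counts
    factors = size_factors(counts)
    if dispersion is None:
        dispersion = estimate_dispersion(counts, factors, exp.samples["condition"])
    X, cond_ix = _design_matrix(exp.samples, contrast, batch_covariate)
    offset = np.log(factors.to_numpy())

    mat = counts.to_numpy(dtype=float)
    norm = mat / factors.to_numpy()[None, :]
    base_mean = norm.mean(axis=1)
    n_genes = mat.shape[0]
    log2fc = np.zeros(n_genes)
    se = np.full(n_genes, np.nan)
    wald = np.zeros(n_genes)
    pval = np.ones(n_genes)
    converged = np.ones(n_genes, dtype=bool)
    alphas = np.maximum(dispersion.to_numpy(dtype=float), _MIN_ALPHA)

    n_failed = 0
    for g in range(n_genes):
        y = mat[g]
        if y.sum() == 0:
            continue
        beta, beta_se, ok = _irls_nb(y, X, offset, alphas[g])
        if not ok or not np.isfinite(beta_se[cond_ix]) or beta_se[cond_ix] <= 0:
            converged[g] = False
            log2fc[g] = beta[cond_ix] / _LN2
            n_failed += 1
            continue
        log2fc[g] = beta[cond_ix] / _LN2
        se[g] = beta_se[cond_ix] / _LN2
        wald[g] = beta[cond_ix] / beta_se[cond_ix]
        pval[g] = 2.0 * stats.norm.sf(abs(wald[g]))
    if n_failed:
        log.warning("%d gene fits did not converge; their p-values were set to 1", n_failed)

    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald_stat": wald,
            "pvalue": pval,
            "padj": bh_adjust(pval),
            "converged": converged,
        }
    ).reset_index(drop=True)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    padj_(i) = min_{k >= i} (m / k) p_(k), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def call_dats(
    table: pd.DataFrame, padj_cut: float = 0.05, lfc_cut: float = 1.0
) -> pd.DataFrame:
    """Differentially abundant transcripts: padj < padj_cut and
    |log2fc| > lfc_cut, with per-gene direction (+1 up / -1 down)."""
    keep = (table["padj"] < padj_cut) & (table["log2fc"].abs() > lfc_cut)
    out = table.loc[keep, ["gene_id", "log2fc"]].copy()
    out["direction"] = np.sign(out["log2fc"]).astype(int)
    return out[["gene_id", "direction"]].reset_index(drop=True)
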