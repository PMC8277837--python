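"""Expression filtering, normalization and differential expression.

The stage mirrors a conventional bulk RNA-seq workflow: counts are converted
to counts-per-million (CPM), genes expressed below a CPM threshold in too few
samples are dropped, expression is taken to log2(CPM + prior), and a per-gene
linear model of log-expression on condition (plus optional age/sex
covariates) yields a log2 fold change, a two-sided t-test p-value and a
Benjamini–Hochberg adjusted p. Genes with padj <= alpha are called up or down
by the sign of the fold change.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ConfigurationError, CountMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)


def cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million: counts / library size * 1e6, per sample."""
    lib = counts.counts.sum(axis=0)
    zero = lib.index[lib == 0]
    if len(zero):
        raise ConfigurationError(f"all-zero library for sample(s): {list(zero)}")
    return counts.counts / lib * 1e6


def filter_low_expression(
    counts: CountMatrix,
    cpm_threshold: float = 0.5,
    sample_fraction: float = 0.5,
    strict_boundary: bool = False,
) -> CountMatrix:
    """Keep genes with CPM >= threshold in at least ``sample_fraction`` of samples.

    ``strict_boundary=True`` switches the per-sample comparison to a strict
    ``>`` (the alternative reading of the filter rule).
    """
    if cpm_threshold <= 0 or sample_fraction <= 0:
        raise ConfigurationError("cpm_threshold and sample_fraction must be positive")
    c = cpm(counts)
    ok = (c > cpm_threshold) if strict_boundary else (c >= cpm_threshold)
    n_needed = sample_fraction * counts.counts.shape[1]
    keep = ok.sum(axis=1) >= n_needed
    logger.info("CPM filter: %d of %d genes retained", int(keep.sum()), len(keep))
    if not keep.any():
        logger.warning("CPM filter removed every gene")
    return CountMatrix(counts=counts.counts.loc[keep], samples=counts.samples)


def normalize(counts: CountMatrix, prior_count: float = 0.5) -> ExpressionMatrix:
    """log2(CPM + prior_count) expression values."""
    values = np.log2(cpm(counts) + prior_count)
    return ExpressionMatrix(values=values, samples=counts.samples)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ConfigurationError("NaN p-values passed to BH adjustment")
    if (p < 0).any() or (p > 1).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _design_matrix(samples: pd.DataFrame, use_covariates: bool) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(samples)), (samples["condition"] == "case").to_numpy(float)]
    names = ["intercept", "condition"]
    if use_covariates:
        if "age" in samples.columns:
            age = samples["age"].to_numpy(float)
            cols.append(age - age.mean())
            names.append("age")
        if "sex" in samples.columns:
            cols.append((samples["sex"] == "M").to_numpy(float))
            names.append("sex")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for j in range(2, X.shape[1]):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == sub.shape[1]:
                raise ConfigurationError(f"collinear design: covariate '{names[j]}'")
        raise ConfigurationError("collinear design matrix")
    return X, names


def differential_expression(
    expr: ExpressionMatrix,
    alpha_de: float = 0.1,
    use_covariates: bool = True,
) -> pd.DataFrame:
    """Per-gene OLS of log2 expression on condition (+ covariates).

    Returns a table indexed by gene with columns log2FC (condition
    coefficient, case vs control), pvalue, padj and status in {up, down, ns}.
    Genes with zero residual variance get p = 1.
    """
    samples = expr.samples.loc[list(expr.values.columns)]
    for cond in ("case", "control"):
        if (samples["condition"] == cond).sum() < 2:
            raise ConfigurationError(f"need >=2 samples in condition '{cond}'")
    X, _ = _design_matrix(samples, use_covariates)
    Y = expr.values.to_numpy(float).T  # samples x genes
    n, p = X.shape
    if n <= p:
        raise ConfigurationError(f"not enough samples ({n}) for {p} design columns")
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / (n - p)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    lfc = beta[1]
    constant = Y.max(axis=0) == Y.min(axis=0)  # no variation at all: no signal
    lfc = np.where(constant, 0.0, lfc)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df=n - p)
    pvals = np.where((se > 0) & ~constant, pvals, 1.0)
    padj = benjamini_hochberg(pvals)
    status = np.where(
        (padj <= alpha_de) & (lfc > 0), "up", np.where((padj <= alpha_de) & (lfc < 0), "down", "ns")
    )
    table = pd.DataFrame(
        {"log2FC": lfc, "pvalue": pvals, "padj": padj, "status": status},
        index=expr.values.index,
    )
    table.index.name = "gene_id"
    logger.info(
        "DE: %d up, %d down at padj <= %g",
        int((table["status"] == "up").sum()), int((table["status"] == "down").sum()), alpha_de,
    )
    return table


def deg_ids(de_table: pd.DataFrame, alpha_de: float = 0.1) -> list[str]:
    """Genes called differentially expressed at the given adjusted level."""
    return list(de_table.index[de_table["padj"] <= alpha_de])
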