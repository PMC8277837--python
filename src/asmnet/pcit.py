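"""PCIT co-expression networks, edge filtering, hubs and scale-free fit.

PCIT (partial correlation and information theory) prunes a Pearson
correlation matrix by examining every trio of genes (x, y, z). For a trio,
the first-order partial correlation of x and y given z is

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) * (1 - r_yz^2))

and the data-driven tolerance is the average ratio of partial to marginal
correlation over the three rotations:

    eps_xyz = (r_xy.z / r_xy + r_xz.y / r_xz + r_yz.x / r_yz) / 3

The pair (x, y) is eliminated if some third gene z satisfies both
|r_xy| < |eps_xyz * r_xz| and |r_xy| < |eps_xyz * r_yz|; pairs never
eliminated by any z are declared significant. The vectorized implementation
below is arithmetically identical to that O(n^3) definition (one z at a
time, whole-matrix inner ops), with two documented guards: correlation legs
are clipped to |r| <= 1 - 1e-12 inside the partial-correlation formulas, and
a ratio term with a zero denominator contributes 0 to eps.

Surviving pairs are then filtered to the reporting network: |r| >= r_min, a
per-edge correlation t-test p < alpha (t = r * sqrt((n-2)/(1-r^2)), df =
n-2), and at least one endpoint in the anchor set (DEGs and TFs). Hubs are
nodes whose degree strictly exceeds mean + 2 SD of the degree distribution,
and the degree distribution is summarized by the R^2 of a log-log fit
(scale-free topology).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigurationError, ExpressionMatrix

logger = logging.getLogger(__name__)

_CLIP = 1.0 - 1e-12


def correlation_matrix(expr: ExpressionMatrix, condition: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Pearson correlation matrix within one condition.

    Returns (r, valid) where ``valid`` flags genes with nonzero variance;
    invalid genes get r = 0 off-diagonal and are excluded from PCIT trios.
    """
    cols = expr.condition_samples(condition)
    if len(cols) < 3:
        raise ConfigurationError(f"condition '{condition}' has {len(cols)} samples; need >=3")
    X = expr.values[cols].to_numpy(float)
    valid = X.var(axis=1) > 0
    if not valid.all():
        logger.warning("%d zero-variance gene(s) in '%s'; correlations set to 0", int((~valid).sum()), condition)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(X)
    r = np.where(np.outer(valid, valid), r, 0.0)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=expr.values.index, columns=expr.values.index), valid


def pcit_significance(r: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Boolean matrix of PCIT-surviving pairs (symmetric, False diagonal).

    Ratio terms of eps use precomputed reciprocals (a zero marginal
    correlation contributes 0); r_yz.x is obtained as the transpose of
    r_xz.y, which is an exact identity of the formula.
    """
    R = np.asarray(r, dtype=float)
    n = R.shape[0]
    if R.shape != (n, n) or n < 3:
        raise ConfigurationError("need a square correlation matrix with >=3 genes")
    if valid is None:
        valid = np.ones(n, dtype=bool)
    Rc = np.clip(R, -_CLIP, _CLIP)
    absR = np.abs(R)
    inv_R = np.where(Rc != 0.0, 1.0 / np.where(Rc != 0.0, Rc, 1.0), 0.0)
    s_one_m = np.sqrt(1.0 - Rc * Rc)  # sqrt(1 - r_xy^2), z-independent
    keep = np.outer(valid, valid)
    np.fill_diagonal(keep, False)
    if (Rc == 0).any():
        logger.info("PCIT: zero marginal correlations present; their eps ratio terms contribute 0")
    # per-z scratch buffers (the loop is memory-bandwidth bound)
    buf = np.empty((4, n, n))
    for z in range(n):
        if not valid[z]:
            continue
        a = Rc[:, z]
        u = 1.0 - a * a
        su = np.sqrt(u)
        inv_a = np.where(a != 0.0, 1.0 / np.where(a != 0.0, a, 1.0), 0.0)
        # t1 = r_xy.z / r_xy
        np.outer(a, a, out=buf[0])
        np.subtract(Rc, buf[0], out=buf[0])
        np.outer(su, su, out=buf[1])
        np.divide(buf[0], buf[1], out=buf[0])
        np.multiply(buf[0], inv_R, out=buf[0])
        # t2 = r_xz.y / r_xz ; t3 = r_yz.x / r_yz = t2 transposed
        np.multiply(Rc, a[None, :], out=buf[1])
        np.subtract(a[:, None], buf[1], out=buf[1])
        np.multiply(s_one_m, su[None, :], out=buf[2])
        np.divide(buf[1], buf[2], out=buf[1])
        np.multiply(buf[1], inv_a[:, None], out=buf[1])
        # eps = (t1 + t2 + t3) / 3
        np.add(buf[0], buf[1], out=buf[0])
        np.add(buf[0], buf[1].T, out=buf[0])
        np.divide(buf[0], 3.0, out=buf[0])
        # eliminate (x, y) when |r_xy| < |eps * r_xz| and |r_xy| < |eps * r_yz|
        np.multiply(buf[0], a[:, None], out=buf[1])
        np.abs(buf[1], out=buf[1])
        np.multiply(buf[0], a[None, :], out=buf[2])
        np.abs(buf[2], out=buf[2])
        elim = (absR < buf[1]) & (absR < buf[2])
        elim[z, :] = False
        elim[:, z] = False
        keep &= ~elim
    np.fill_diagonal(keep, False)
    return keep


def correlation_pvalues(r: np.ndarray, n_samples: int) -> np.ndarray:
    """Two-sided t-test p-values for Pearson correlations (df = n - 2)."""
    r = np.asarray(r, dtype=float)
    rc = np.clip(r, -_CLIP, _CLIP)
    t = np.abs(rc) * np.sqrt((n_samples - 2) / (1.0 - rc**2))
    return 2.0 * stats.t.sf(t, df=n_samples - 2)


def build_network(
    corr: pd.DataFrame,
    pcit_mask: np.ndarray,
    anchor_genes,
    n_samples: int,
    r_min: float = 0.95,
    alpha_r: float = 0.05,
    condition: str | None = None,
) -> pd.DataFrame:
    """Edge list of PCIT-significant, |r| >= r_min, p < alpha, anchor-incident pairs."""
    if not 0 < r_min <= 1:
        raise ConfigurationError(f"r_min must lie in (0, 1], got {r_min}")
    anchors = set(anchor_genes)
    if not anchors:
        raise ConfigurationError("empty anchor set")
    genes = np.asarray(corr.index)
    R = corr.to_numpy(float)
    is_anchor = np.isin(genes, list(anchors))
    sel = (
        np.triu(pcit_mask, k=1)
        & (np.abs(R) >= r_min)
        & (is_anchor[:, None] | is_anchor[None, :])
    )
    ia, ib = np.nonzero(sel)
    rvals = R[ia, ib]
    pvals = correlation_pvalues(rvals, n_samples)
    ok = pvals < alpha_r
    edges = pd.DataFrame(
        {
            "gene_a": genes[ia][ok],
            "gene_b": genes[ib][ok],
            "r": rvals[ok],
            "p": pvals[ok],
        }
    )
    if condition is not None:
        edges["condition"] = condition
    edges = edges.sort_values(["gene_a", "gene_b"], ignore_index=True)
    logger.info("network%s: %d edges over %d anchors", f" ({condition})" if condition else "", len(edges), len(anchors))
    return edges


def degree_series(edges: pd.DataFrame) -> pd.Series:
    nodes = pd.concat([edges["gene_a"], edges["gene_b"]])
    deg = nodes.value_counts().sort_index()
    deg.name = "degree"
    deg.index.name = "gene_id"
    return deg


def hub_genes(edges: pd.DataFrame, n_sd: float = 2.0, ddof: int = 1) -> pd.DataFrame:
    """Degree table with hub calls: degree > mean + n_sd * SD (strict)."""
    if len(edges) == 0:
        raise ConfigurationError("empty network: no degrees to analyze")
    deg = degree_series(edges)
    if len(deg) < 2:
        logger.warning("single-node network: no hubs")
        thresh = np.inf
    else:
        thresh = deg.mean() + n_sd * deg.std(ddof=ddof)
    report = deg.to_frame()
    report["is_hub"] = deg > thresh
    report.attrs["threshold"] = float(thresh)
    return report.sort_values("degree", ascending=False)


def scale_free_r2(degrees, n_bins: int = 10) -> float:
    """R^2 of log10 P(k) on log10 k over log-spaced degree bins.

    Returns NaN (with a warning) when fewer than 3 bins are occupied.
    """
    k = np.asarray(degrees, dtype=float)
    k = k[k > 0]
    if k.size == 0 or np.unique(k).size < 3:
        logger.warning("scale-free fit undefined: fewer than 3 distinct degrees")
        return float("nan")
    edges = np.logspace(np.log10(k.min()), np.log10(k.max()), n_bins + 1)
    edges[-1] *= 1 + 1e-9  # right-closed last bin
    counts, _ = np.histogram(k, bins=edges)
    nonempty = counts > 0
    if nonempty.sum() < 3:
        logger.warning("scale-free fit undefined: fewer than 3 nonempty bins")
        return float("nan")
    # bin abscissa: mean log-degree of members, exact when a bin holds one degree
    which = np.digitize(k, edges[1:-1], right=False)
    logk = np.log10(k)
    xs = np.array([logk[which == b].mean() for b in np.nonzero(nonempty)[0]])
    ys = np.log10(counts[nonempty] / k.size)
    fit = stats.linregress(xs, ys)
    return float(fit.rvalue**2)


def scale_free_fit(edges: pd.DataFrame, n_bins: int = 10) -> float:
    return scale_free_r2(degree_series(edges).to_numpy(), n_bins=n_bins)
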