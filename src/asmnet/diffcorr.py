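"""Differential correlation of gene pairs between two conditions.

For a pair of genes with within-condition Pearson correlations r_case and
r_control, the Fisher z-transform z = atanh(r) is approximately normal with
variance 1/(n-3), so the difference statistic

    z_diff = (atanh(r_case) - atanh(r_control))
             / sqrt(1/(n_case - 3) + 1/(n_control - 3))

is standard normal under the null of equal population correlations; its
two-sided tail gives pval_diff, BH-adjusted over all tested pairs. Each pair
is also assigned one of nine classes written "case/control", where each side
is '+' (r > 0, correlation t-test p <= class_alpha), '-' (r < 0, p <=
class_alpha) or '0' (not significant).

Note the test is weak at very small group sizes: with n = 5 per group the
variance term 1/(n-3) is 0.5 per condition, and a warning is emitted when
either group has fewer than 10 samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigurationError, ExpressionMatrix
from .pcit import correlation_pvalues
from .preprocess import benjamini_hochberg

logger = logging.getLogger(__name__)

_CLIP = 1.0 - 1e-12

CLASS_LABELS = ("+/+", "+/-", "+/0", "-/+", "-/0", "-/-", "0/+", "0/0", "0/-")


def fisher_z_difference(r_case, n_case: int, r_control, n_control: int):
    """(z_diff, pval_diff) for the difference of two correlations; array-safe."""
    if n_case < 4 or n_control < 4:
        raise ConfigurationError("need n >= 4 per condition (Fisher variance undefined)")
    rc = np.clip(np.asarray(r_case, dtype=float), -_CLIP, _CLIP)
    rk = np.clip(np.asarray(r_control, dtype=float), -_CLIP, _CLIP)
    if np.any(np.abs(np.asarray(r_case)) >= 1) or np.any(np.abs(np.asarray(r_control)) >= 1):
        logger.warning("|r| >= 1 clipped before Fisher transform")
    se = np.sqrt(1.0 / (n_case - 3) + 1.0 / (n_control - 3))
    z = (np.arctanh(rc) - np.arctanh(rk)) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    if np.ndim(r_case) == 0 and np.ndim(r_control) == 0:
        return float(z), float(p)
    return z, p


def _side(r: float, p: float, class_alpha: float) -> str:
    if p <= class_alpha:
        if r > 0:
            return "+"
        if r < 0:
            return "-"
    return "0"


def classify_pair(
    r_case: float, p_case: float, r_control: float, p_control: float, class_alpha: float = 0.05
) -> str:
    """Nine-class label "case/control" with sides '+', '-' or '0'."""
    return f"{_side(r_case, p_case, class_alpha)}/{_side(r_control, p_control, class_alpha)}"


def _cond_arrays(expr: ExpressionMatrix, condition: str) -> np.ndarray:
    X = expr.condition_values(condition).to_numpy(float)
    return X


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Xc = X - X.mean(axis=1, keepdims=True)
    ss = np.sqrt((Xc**2).sum(axis=1))
    ok = ss > 0
    Xs = np.where(ok[:, None], Xc / np.where(ok, ss, 1.0)[:, None], 0.0)
    return Xs, ok


def differential_coexpression_scan(
    expr: ExpressionMatrix,
    anchor_genes=None,
    alpha_adj: float = 0.05,
    class_alpha: float = 0.05,
    block_size: int = 512,
) -> pd.DataFrame:
    """Fisher-z differential-correlation scan over a pair universe.

    ``anchor_genes=None`` scans all gene pairs; otherwise only pairs with at
    least one anchor endpoint. Evaluation is blocked so memory stays bounded
    in the number of genes, not pairs. Pairs involving a constant gene are
    skipped (count logged).
    """
    genes = np.asarray(expr.values.index)
    n_case = len(expr.condition_samples("case"))
    n_control = len(expr.condition_samples("control"))
    if n_case < 4 or n_control < 4:
        raise ConfigurationError("need >=4 samples per condition")
    if min(n_case, n_control) < 10:
        logger.warning(
            "small groups (%d/%d): the Fisher z test has little power below ~10 samples/group",
            n_case, n_control,
        )
    Xc, ok_c = _standardize(_cond_arrays(expr, "case"))
    Xk, ok_k = _standardize(_cond_arrays(expr, "control"))
    usable = ok_c & ok_k
    n_skipped_const = int((~usable).sum())
    if n_skipped_const:
        logger.info("skipping pairs of %d constant gene(s)", n_skipped_const)
    if anchor_genes is None:
        anchored = np.ones(len(genes), dtype=bool)
    else:
        anchored = np.isin(genes, list(set(anchor_genes)))

    se = np.sqrt(1.0 / (n_case - 3) + 1.0 / (n_control - 3))
    chunks: list[pd.DataFrame] = []
    n_genes = len(genes)
    for a0 in range(0, n_genes, block_size):
        a1 = min(a0 + block_size, n_genes)
        rc_blk = np.clip(Xc[a0:a1] @ Xc.T, -1.0, 1.0)
        rk_blk = np.clip(Xk[a0:a1] @ Xk.T, -1.0, 1.0)
        ii, jj = np.nonzero(
            (np.arange(a0, a1)[:, None] < np.arange(n_genes)[None, :])
            & usable[a0:a1, None]
            & usable[None, :]
            & (anchored[a0:a1, None] | anchored[None, :])
        )
        if len(ii) == 0:
            continue
        rcs = rc_blk[ii, jj]
        rks = rk_blk[ii, jj]
        zdiff = (np.arctanh(np.clip(rcs, -_CLIP, _CLIP)) - np.arctanh(np.clip(rks, -_CLIP, _CLIP))) / se
        pdiff = 2.0 * stats.norm.sf(np.abs(zdiff))
        pc = correlation_pvalues(rcs, n_case)
        pk = correlation_pvalues(rks, n_control)
        chunks.append(
            pd.DataFrame(
                {
                    "gene_a": genes[ii + a0],
                    "gene_b": genes[jj],
                    "r_case": rcs,
                    "r_control": rks,
                    "p_case": pc,
                    "p_control": pk,
                    "z_diff": zdiff,
                    "pval_diff": pdiff,
                }
            )
        )
    if not chunks:
        raise ConfigurationError("empty pair universe")
    records = pd.concat(chunks, ignore_index=True)
    records["pval_diff_adj"] = benjamini_hochberg(records["pval_diff"].to_numpy())
    case_side = np.where(
        (records["p_case"] <= class_alpha) & (records["r_case"] > 0), "+",
        np.where((records["p_case"] <= class_alpha) & (records["r_case"] < 0), "-", "0"),
    )
    control_side = np.where(
        (records["p_control"] <= class_alpha) & (records["r_control"] > 0), "+",
        np.where((records["p_control"] <= class_alpha) & (records["r_control"] < 0), "-", "0"),
    )
    records["class"] = pd.Series(case_side, index=records.index).str.cat(
        pd.Series(control_side, index=records.index), sep="/"
    )
    records["significant"] = records["pval_diff_adj"] <= alpha_adj
    logger.info(
        "diff-corr scan: %d pairs tested, %d significant at padj <= %g",
        len(records), int(records["significant"].sum()), alpha_adj,
    )
    return records


def class_counts(records: pd.DataFrame, significant_only: bool = False) -> dict[str, int]:
    sub = records[records["significant"]] if significant_only else records
    counts = sub["class"].value_counts().to_dict()
    return {lbl: int(counts.get(lbl, 0)) for lbl in CLASS_LABELS}


def all_class_labels() -> tuple[str, ...]:
    return CLASS_LABELS
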