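"""Regulatory Impact Factor (RIF) scoring of transcription factors.

RIF ranks candidate regulators by how differently they are wired to the
differentially expressed genes (DEGs) in two conditions. For each DE gene j
let e1_j, e2_j be its mean expression in case and control, a_j their average,
dE_j = e1_j - e2_j, and PIF_j = a_j * dE_j (the phenotype impact factor:
abundance-weighted differential expression). For each TF i, with r1_ij, r2_ij
the within-condition Pearson correlations to gene j and DW_ij = r1_ij - r2_ij
the differential wiring:

    RIF1_i = (1/n_de) * sum_j PIF_j * DW_ij^2
    RIF2_i = (1/n_de) * sum_j [(e1_j * r1_ij)^2 - (e2_j * r2_ij)^2]

RIF1 favours TFs most differentially co-expressed with abundant DEGs; RIF2
favours TFs whose ability to predict DEG abundance changes most. Raw scores
are z-standardized across scored TFs and a TF is flagged significant when
either |z| reaches the threshold (2 by convention).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ConfigurationError, ExpressionMatrix

logger = logging.getLogger(__name__)


def _corr_block(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlations between rows of A and rows of B (same samples)."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((Ac**2).sum(axis=1))
    sb = np.sqrt((Bc**2).sum(axis=1))
    denom = np.outer(sa, sb)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Ac @ Bc.T) / denom
    return np.clip(r, -1.0, 1.0)


def rif_scores(
    expr: ExpressionMatrix,
    tf_ids,
    deg_ids,
    z_thresh: float = 2.0,
) -> pd.DataFrame:
    """Score TFs against the DEG set; returns a table indexed by TF.

    Condition 1 is "case", condition 2 "control" (positive dE_j means higher
    in case). TFs with zero variance within either condition are dropped with
    a warning; a gene appearing in both lists contributes in both roles but
    its self-pair is excluded from the sums.
    """
    genes = set(expr.values.index)
    tfs = [t for t in tf_ids if t in genes]
    degs = [d for d in deg_ids if d in genes]
    if not degs:
        raise ConfigurationError("empty DEG set: RIF undefined")
    if len(tfs) < 2:
        raise ConfigurationError("need at least 2 TFs to z-standardize RIF scores")
    for cond in ("case", "control"):
        if len(expr.condition_samples(cond)) < 4:
            raise ConfigurationError(f"need >=4 samples in condition '{cond}' for correlations")

    Xc = expr.condition_values("case")
    Xk = expr.condition_values("control")
    Tc, Tk = Xc.loc[tfs].to_numpy(float), Xk.loc[tfs].to_numpy(float)
    Dc, Dk = Xc.loc[degs].to_numpy(float), Xk.loc[degs].to_numpy(float)

    # drop TFs that are constant within a condition (correlation undefined)
    var_ok = (Tc.var(axis=1) > 0) & (Tk.var(axis=1) > 0)
    if not var_ok.all():
        dropped = [t for t, ok in zip(tfs, var_ok) if not ok]
        logger.warning("dropping %d zero-variance TF(s): %s", len(dropped), dropped[:10])
        tfs = [t for t, ok in zip(tfs, var_ok) if ok]
        Tc, Tk = Tc[var_ok], Tk[var_ok]
        if len(tfs) < 2:
            raise ConfigurationError("fewer than 2 TFs with defined correlations")
    deg_var_ok = (Dc.var(axis=1) > 0) & (Dk.var(axis=1) > 0)

    e1, e2 = Dc.mean(axis=1), Dk.mean(axis=1)
    a = (e1 + e2) / 2.0
    dE = e1 - e2
    pif = a * dE

    r1 = _corr_block(Tc, Dc)
    r2 = _corr_block(Tk, Dk)
    r1 = np.where(deg_var_ok[None, :], r1, 0.0)
    r2 = np.where(deg_var_ok[None, :], r2, 0.0)
    dw = r1 - r2

    rif1_terms = pif[None, :] * dw**2
    rif2_terms = (e1[None, :] * r1) ** 2 - (e2[None, :] * r2) ** 2

    # a gene that is both TF and DEG: exclude the self-pair from the sums
    tf_pos = {t: i for i, t in enumerate(tfs)}
    for j, d in enumerate(degs):
        if d in tf_pos:
            rif1_terms[tf_pos[d], j] = 0.0
            rif2_terms[tf_pos[d], j] = 0.0

    n_de = len(degs)
    rif1 = rif1_terms.sum(axis=1) / n_de
    rif2 = rif2_terms.sum(axis=1) / n_de

    def zscore(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=1)
        if sd == 0:
            logger.warning("degenerate RIF scores (zero spread); z set to 0")
            return np.zeros_like(v)
        return (v - v.mean()) / sd

    z1, z2 = zscore(rif1), zscore(rif2)
    table = pd.DataFrame(
        {
            "rif1_raw": rif1,
            "rif2_raw": rif2,
            "rif1_z": z1,
            "rif2_z": z2,
            "significant": (np.abs(z1) >= z_thresh) | (np.abs(z2) >= z_thresh),
        },
        index=pd.Index(tfs, name="tf_id"),
    )
    logger.info("RIF: %d of %d TFs significant at |z| >= %g", int(table["significant"].sum()), len(tfs), z_thresh)
    return table


def significant_tfs(rif_table: pd.DataFrame) -> list[str]:
    return list(rif_table.index[rif_table["significant"]])
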