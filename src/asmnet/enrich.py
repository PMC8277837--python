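"""Gene-set over-representation analysis and redundancy grouping.

Enrichment of a query gene list in user-supplied gene sets (GMT) is tested
with the one-sided hypergeometric tail P(X >= overlap) against a declared
universe, BH-adjusted across terms. Redundant significant terms are grouped
by Cohen's kappa of their query-membership indicator vectors (terms joined
when kappa >= kappa_min, clusters by single linkage). A plain, case-
normalized set intersection against curated marker lists is also provided.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigurationError

logger = logging.getLogger(__name__)


def hypergeometric_ora(
    query,
    sets: dict[str, tuple[str, set[str]]],
    universe,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of ``query`` within ``universe``.

    Query genes outside the universe are dropped (count logged); set members
    are intersected with the universe before testing.
    """
    universe = set(universe)
    if not universe:
        raise ConfigurationError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        logger.info("dropping %d query gene(s) outside the universe", len(outside))
        query &= universe
    M, n_query = len(universe), len(query)
    rows = []
    for term, (desc, members) in sets.items():
        members_u = members & universe
        overlap = len(members_u & query)
        k_set = len(members_u)
        # P(X >= overlap); sf is exclusive, hence overlap - 1
        p = float(stats.hypergeom.sf(overlap - 1, M, k_set, n_query)) if k_set else 1.0
        rows.append(
            {
                "term_id": term,
                "description": desc,
                "overlap": overlap,
                "set_size": k_set,
                "query_size": n_query,
                "universe_size": M,
                "pvalue": min(p, 1.0),
            }
        )
    records = pd.DataFrame(
        rows,
        columns=["term_id", "description", "overlap", "set_size", "query_size", "universe_size", "pvalue"],
    )
    from .preprocess import benjamini_hochberg

    records["padj"] = benjamini_hochberg(records["pvalue"].to_numpy()) if len(records) else []
    return records.sort_values(["pvalue", "term_id"], ignore_index=True)


def cohen_kappa(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's kappa between two binary vectors; 1.0 when both are identical
    and constant (perfect, if degenerate, agreement), 0.0 for degenerate
    disagreement beyond chance."""
    x = np.asarray(x, bool)
    y = np.asarray(y, bool)
    n = x.size
    po = float((x == y).mean())
    pe = float(x.mean() * y.mean() + (1 - x.mean()) * (1 - y.mean()))
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def kappa_grouping(
    records: pd.DataFrame,
    sets: dict[str, tuple[str, set[str]]],
    query,
    kappa_min: float = 0.4,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Assign group ids to significant terms by single-linkage kappa clustering.

    Kappa is computed over the query genes' term-membership indicators (the
    convention of kappa-based term-grouping tools). Group ids are
    deterministic: components are numbered
    by their lexicographically smallest term.
    """
    query = sorted(set(query))
    pcol = "padj" if use_adjusted else "pvalue"
    sig = records[records[pcol] <= alpha] if len(records) else records
    out = records.copy()
    out["group_id"] = -1
    if len(sig) == 0:
        logger.warning("no significant terms to group")
        return out
    terms = sorted(sig["term_id"])
    vecs = {t: np.array([g in sets[t][1] for g in query]) for t in terms}
    parent = {t: t for t in terms}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for a, b in combinations(terms, 2):
        if cohen_kappa(vecs[a], vecs[b]) >= kappa_min:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    roots = sorted({find(t) for t in terms})
    gid = {root: i for i, root in enumerate(roots)}
    mapping = {t: gid[find(t)] for t in terms}
    out["group_id"] = out["term_id"].map(mapping).fillna(-1).astype(int)
    return out


def marker_intersection(genes, markers) -> pd.DataFrame:
    """Case-normalized intersection of a gene list with a curated marker list."""
    gmap = {str(g).upper(): g for g in genes}
    mset = {str(m).upper() for m in markers}
    common = sorted(set(gmap) & mset)
    result = pd.DataFrame({"gene_id": [gmap[c] for c in common]})
    result.attrs["n_query"] = len(set(genes))
    result.attrs["n_markers"] = len(set(markers))
    logger.info("marker intersection: %d of %d query genes in %d markers", len(result), len(set(genes)), len(set(markers)))
    return result
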