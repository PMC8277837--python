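"""Union reference network and differential connectivity (DK).

The case and control edge lists are merged into a central reference (union)
network whose nodes and edges carry a presence flag (case_only,
control_only, shared). Per gene, connectivity is standardized within each
condition as K = k / max(k); the differential connectivity is

    DK_i = K_case(i) - K_control(i)

(genes absent from one condition's network count degree 0 there). DK is
z-scored over all union genes and a gene is called a connectivity gain when
z >= +z_thresh and a loss when z <= -z_thresh (1.96 by convention, the
two-sided 5% boundary of the standard normal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ConfigurationError
from .pcit import degree_series

logger = logging.getLogger(__name__)


def _edge_keys(edges: pd.DataFrame) -> set[tuple[str, str]]:
    return {tuple(sorted((a, b))) for a, b in zip(edges["gene_a"], edges["gene_b"])}


@dataclass
class UnionNetwork:
    """Merged case/control network with presence flags."""

    nodes: pd.DataFrame  # columns: gene_id, presence
    edges: pd.DataFrame  # columns: gene_a, gene_b, presence
    case_edges: pd.DataFrame
    control_edges: pd.DataFrame


def _flag(in_case: bool, in_control: bool) -> str:
    if in_case and in_control:
        return "shared"
    return "case_only" if in_case else "control_only"


def union_network(case_edges: pd.DataFrame, control_edges: pd.DataFrame) -> UnionNetwork:
    if len(case_edges) == 0 or len(control_edges) == 0:
        raise ConfigurationError("both edge lists must be nonempty")
    ce, ke = _edge_keys(case_edges), _edge_keys(control_edges)
    edge_rows = [
        {"gene_a": a, "gene_b": b, "presence": _flag((a, b) in ce, (a, b) in ke)}
        for a, b in sorted(ce | ke)
    ]
    cn = {g for e in ce for g in e}
    kn = {g for e in ke for g in e}
    node_rows = [{"gene_id": g, "presence": _flag(g in cn, g in kn)} for g in sorted(cn | kn)]
    un = UnionNetwork(
        nodes=pd.DataFrame(node_rows, columns=["gene_id", "presence"]),
        edges=pd.DataFrame(edge_rows, columns=["gene_a", "gene_b", "presence"]),
        case_edges=case_edges,
        control_edges=control_edges,
    )
    logger.info(
        "union network: %d nodes, %d edges (%d shared edges)",
        len(un.nodes), len(un.edges), sum(r["presence"] == "shared" for r in edge_rows),
    )
    return un


def differential_connectivity(
    union: UnionNetwork,
    z_thresh: float = 1.96,
    center: bool = True,
    ddof: int = 1,
) -> pd.DataFrame:
    """Connectivity table over the union gene set.

    ``center=False`` z-scores raw DK about 0 rather than its mean; ``ddof``
    selects sample (1) vs population (0) SD. Both defaults follow the
    standard two-sided reading of the +/-1.96 SD rule.
    """
    genes = union.nodes["gene_id"]
    k_case = degree_series(union.case_edges).reindex(genes, fill_value=0).to_numpy(float)
    k_control = degree_series(union.control_edges).reindex(genes, fill_value=0).to_numpy(float)
    if k_case.max() == 0 or k_control.max() == 0:
        raise ConfigurationError("max degree must be positive in both conditions")
    K_case = k_case / k_case.max()
    K_control = k_control / k_control.max()
    dk = K_case - K_control
    sd = np.std(dk, ddof=ddof)
    if sd == 0:
        logger.warning("zero spread in DK; all calls 'ns'")
        z = np.zeros_like(dk)
    else:
        z = (dk - dk.mean()) / sd if center else dk / sd
    call = np.where(z >= z_thresh, "gain", np.where(z <= -z_thresh, "loss", "ns"))
    if sd == 0:
        call = np.full_like(call, "ns")
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "k_case": k_case.astype(int),
            "k_control": k_control.astype(int),
            "K_case": K_case,
            "K_control": K_control,
            "DK": dk,
            "z": z,
            "call": call,
        }
    )
    logger.info(
        "differential connectivity: %d gain, %d loss of %d union genes",
        int((table["call"] == "gain").sum()), int((table["call"] == "loss").sum()), len(table),
    )
    return table
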