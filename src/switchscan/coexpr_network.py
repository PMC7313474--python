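"""Signed Pearson co-expression network on the filtered gene set.

Edges connect gene pairs whose expression profiles are significantly
correlated or anti-correlated: the pair must pass both a hard |PCC| floor and
a BH-adjusted significance test (t-transform of r with n-2 degrees of
freedom).  Weights keep their sign, which is what later distinguishes fight
club hubs (negative average neighbour correlation) from date/party hubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .deg_filter import benjamini_hochberg
from .expr_io import ExpressionMatrix

logger = logging.getLogger("switchscan")


class NetworkError(ValueError):
    pass


@dataclass
class CorrelationNetwork:
    """Undirected signed co-expression graph.

    ``graph`` is a networkx Graph whose nodes are the retained genes (isolated
    nodes flagged with the ``isolated`` attribute) and whose edges carry the
    signed Pearson coefficient as ``weight`` plus the BH-adjusted edge q-value.
    ``params`` records the edge criterion actually used.
    """

    graph: nx.Graph
    params: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, node: str) -> list[str]:
        return list(self.graph.neighbors(node))

    def edge_weight(self, a: str, b: str) -> float:
        return float(self.graph.edges[a, b]["weight"])

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            (a, b, d["weight"], d.get("q", np.nan))
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcc", "q_edge"])


def correlation_matrix(
    em: ExpressionMatrix, sample_scope: str = "all"
) -> pd.DataFrame:
    """Pairwise Pearson correlation between gene expression profiles.

    ``sample_scope`` selects the columns correlated over: ``"all"`` (cases and
    controls) or ``"case_only"``.
    """
    if sample_scope == "all":
        cols = em.sample_ids
    elif sample_scope == "case_only":
        cols = em.samples_of("case")
    else:
        raise NetworkError(f"unknown sample_scope {sample_scope!r}")
    if len(cols) < 3:
        raise NetworkError(f"need >=3 samples in scope, have {len(cols)}")
    x = em.data[cols].to_numpy(dtype=float)
    sd = x.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise NetworkError(
            f"zero-variance gene in correlation scope: {em.gene_ids[flat[0]]!r}"
        )
    corr = np.corrcoef(x)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=em.data.index, columns=em.data.index)


def correlation_pvalues(corr: np.ndarray, n_samples: int) -> np.ndarray:
    """Two-sided p-values for Pearson r via the t-transform, n-2 df."""
    if n_samples < 3:
        raise NetworkError("need n_samples >= 3 for correlation significance")
    df = n_samples - 2
    r = np.clip(np.asarray(corr, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def build_network(
    corr: pd.DataFrame,
    pcc_floor: float = 0.6,
    alpha_edge: float = 0.05,
    n_samples: int | None = None,
) -> CorrelationNetwork:
    """Threshold the correlation matrix into a signed network.

    An edge (i, j) is kept iff ``|PCC| >= pcc_floor`` (closed rule: equality
    keeps the edge) and the BH-adjusted correlation p-value is below
    ``alpha_edge``.  All genes stay in the node set; genes left without edges
    are flagged isolated.
    """
    if n_samples is None:
        raise NetworkError("n_samples is required for edge significance")
    if not 0 <= pcc_floor <= 1:
        raise NetworkError(f"pcc_floor must be in [0,1], got {pcc_floor}")
    genes = list(corr.index)
    r = corr.to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(genes), k=1)
    rvec = r[iu, ju]
    q = benjamini_hochberg(correlation_pvalues(rvec, n_samples))
    keep = (np.abs(rvec) >= pcc_floor) & (q < alpha_edge)
    if not keep.any():
        raise NetworkError(
            f"no edge passes |PCC| >= {pcc_floor} at FDR {alpha_edge}; lower the floor"
        )
    g = nx.Graph()
    g.add_nodes_from(genes)
    for i, j, w, qe in zip(iu[keep], ju[keep], rvec[keep], q[keep]):
        g.add_edge(genes[i], genes[j], weight=float(w), q=float(qe))
    for node in g.nodes:
        g.nodes[node]["isolated"] = g.degree(node) == 0
    logger.info(
        "network: %d nodes, %d edges (|PCC|>=%.2f, FDR %.3g, n=%d)",
        len(genes), g.number_of_edges(), pcc_floor, alpha_edge, n_samples,
    )
    return CorrelationNetwork(
        g,
        params={
            "pcc_floor": pcc_floor,
            "alpha_edge": alpha_edge,
            "n_samples": n_samples,
        },
    )
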