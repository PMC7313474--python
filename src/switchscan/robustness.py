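"""Network robustness under targeted node removal.

The diagnostic is the unweighted average shortest path length (APL) of the
largest connected component, tracked while progressively removing nodes of a
given hub class (or uniformly at random).  Fight club hubs — the anti-
correlated connectors — are expected to damage the network disproportionately,
which is what makes them stand out against random removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, shortest_path

from .coexpr_network import CorrelationNetwork

logger = logging.getLogger("switchscan")

REMOVAL_CLASSES = ("fight_club", "date", "party", "random")


class RobustnessError(ValueError):
    pass


@dataclass
class RemovalCurve:
    """APL as a function of the removed fraction of one node class."""

    class_label: str
    fractions: np.ndarray
    apl: np.ndarray
    repeats: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"class": self.class_label, "fraction": self.fractions, "apl": self.apl}
        )


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, CorrelationNetwork) else net


def average_shortest_path(net) -> float:
    """Mean unweighted shortest-path length over the largest connected
    component; components of one node (or an empty graph) score 0."""
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        return 0.0
    return _apl_csr(nx.to_scipy_sparse_array(g, weight=None, format="csr"))


def _apl_csr(adj) -> float:
    """APL of the largest component of an unweighted CSR adjacency matrix."""
    if adj.shape[0] == 0:
        return 0.0
    _, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels)
    giant = np.flatnonzero(labels == sizes.argmax())
    if giant.size <= 1:
        return 0.0
    sub = adj[giant][:, giant]
    d = shortest_path(sub, method="D", unweighted=True, directed=False)
    iu = np.triu_indices(giant.size, k=1)
    return float(d[iu].mean())


def removal_curve(
    net,
    cart: pd.DataFrame,
    class_label: str,
    fraction_grid=None,
    repeats: int = 20,
    seed: int = 0,
    match_class: str | None = None,
) -> RemovalCurve:
    """APL after removing growing random fractions of one node class.

    For each fraction f, ``floor(f * class size)`` class members are removed
    (uniformly at random, seeded) and the APL of what remains is recomputed;
    the curve averages ``repeats`` independent removal orderings.  Nodes
    outside the class are never touched except under ``random``, where the
    class is the whole node set.

    ``match_class`` makes a ``random`` curve a size-matched control: removal
    counts are computed from the named class's size while the removed nodes
    are still drawn from the whole network, so targeted and random curves
    remove the same number of nodes at each fraction.
    """
    g = _as_graph(net)
    fractions = np.asarray(
        np.arange(0.0, 0.501, 0.05) if fraction_grid is None else fraction_grid,
        dtype=float,
    )
    if (fractions > 1).any():
        raise RobustnessError("removal fractions must be <= 1")
    if fractions[0] != 0 or (np.diff(fractions) <= 0).any():
        raise RobustnessError("fraction grid must start at 0 and strictly increase")
    def class_members(label: str) -> list[str]:
        if label == "random":
            return sorted(g.nodes)
        if label not in REMOVAL_CLASSES:
            raise RobustnessError(f"unknown node class {label!r}")
        return sorted(set(cart.index[cart["hub_class"] == label]) & set(g.nodes))

    members = class_members(class_label)
    if not members:
        raise RobustnessError(f"class {class_label!r} has no members in the network")
    size_basis = len(members)
    if match_class is not None:
        if class_label != "random":
            raise RobustnessError("match_class only applies to the random curve")
        size_basis = len(class_members(match_class))
        if size_basis == 0:
            raise RobustnessError(f"match class {match_class!r} has no members")

    rng = np.random.default_rng(seed)
    apl = np.zeros_like(fractions)
    base = average_shortest_path(g)
    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    adj = nx.to_scipy_sparse_array(g, nodelist=nodes, weight=None, format="csr")
    for _ in range(repeats):
        order = rng.permutation(members)
        for fi, f in enumerate(fractions):
            n_remove = min(int(np.floor(f * size_basis)), len(members))
            if n_remove == 0:
                apl[fi] += base
                continue
            gone = {index[n] for n in order[:n_remove]}
            keep = np.array([i for i in range(len(nodes)) if i not in gone])
            apl[fi] += _apl_csr(adj[keep][:, keep])
    apl /= repeats
    return RemovalCurve(class_label, fractions, apl, repeats)


def removal_curves(
    net, cart: pd.DataFrame, classes=REMOVAL_CLASSES, **kwargs
) -> pd.DataFrame:
    """Curves for several classes stacked in one tidy frame; classes with no
    members in the network are skipped with a warning."""
    frames = []
    for cls in classes:
        try:
            frames.append(removal_curve(net, cart, cls, **kwargs).to_frame())
        except RobustnessError as exc:
            logger.warning("skipping removal class %s: %s", cls, exc)
    if not frames:
        raise RobustnessError("no removal class has members")
    return pd.concat(frames, ignore_index=True)
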