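"""Community cartography and switch-gene extraction.

Communities come from replicated k-means on the z-scored expression profiles,
with the community count chosen from the SSE scree curve (elbow = largest
second forward difference).  Each network node then gets three coordinates:

* ``Zg`` — within-module degree z-score (how connected the node is inside its
  own community, relative to that community);
* ``Kpi`` — clusterphobic coefficient ``1 - (internal/total degree)^2``,
  near 1 when most links leave the module;
* ``APCC`` — average signed Pearson correlation with network neighbours.

The Zg-Kpi plane is partitioned into the classical cartographic regions
R1-R7; switch genes are the R4 residents (Zg < 2.5, Kpi > 0.8) whose APCC is
negative, i.e. fight club hubs wired mainly outside their own community.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .coexpr_network import CorrelationNetwork
from .expr_io import ExpressionMatrix

logger = logging.getLogger("switchscan")

HUB_CLASSES = ("date", "party", "fight_club", "none")


class CartographyError(ValueError):
    pass


@dataclass
class CommunityPartition:
    """k-means community assignment (module ids contiguous from 1)."""

    assignment: dict[str, int]
    k: int
    sse: float
    replicate_count: int

    def __post_init__(self) -> None:
        mods = sorted(set(self.assignment.values()))
        if mods != list(range(1, len(mods) + 1)):
            raise CartographyError(f"module ids not contiguous from 1: {mods}")
        if self.sse < 0:
            raise CartographyError("SSE must be >= 0")

    def members(self, module: int) -> list[str]:
        return [g for g, m in self.assignment.items() if m == module]


@dataclass
class CartographyThresholds:
    """Boundaries of the heat-cartography plane.

    ``zg_hub`` separates hubs from non-hubs for the region grid and is the
    switch-rule ceiling; ``zg_strong_hub`` is the stricter hub definition
    reported as a separate flag; ``kpi_switch`` is the R4 boundary;
    ``apcc_party`` splits low-positive (date) from high-positive (party) APCC.
    Non-hub Kpi breakpoints (0.05, 0.62, 0.8) and hub breakpoints (0.30,
    0.75) follow the standard cartographic convention.
    """

    zg_hub: float = 2.5
    kpi_switch: float = 0.8
    apcc_party: float = 0.5
    zg_strong_hub: float = 5.0
    kpi_nonhub_bounds: tuple[float, float, float] = (0.05, 0.62, 0.8)
    kpi_hub_bounds: tuple[float, float] = (0.30, 0.75)


@dataclass
class SwitchGeneSet:
    """Named per-condition switch-gene list (the unit of comparison)."""

    condition: str
    genes: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise CartographyError("switch genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


# ---------------------------------------------------------------------------
# k-means communities
# ---------------------------------------------------------------------------

def _zscore_profiles(em: ExpressionMatrix) -> np.ndarray:
    x = em.values
    sd = x.std(axis=1, ddof=0)
    if (sd == 0).any():
        bad = em.gene_ids[int(np.flatnonzero(sd == 0)[0])]
        raise CartographyError(f"zero-variance profile {bad!r}; pre-filter first")
    return (x - x.mean(axis=1, keepdims=True)) / sd[:, None]


def choose_k_scree(
    em_filtered: ExpressionMatrix,
    k_range: range | list[int] = range(2, 11),
    replicates: int = 20,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the community count from the min-SSE scree curve.

    For every k the clustering is replicated from fresh random centroids and
    the lowest SSE kept; the elbow is the k with the largest second forward
    difference of the min-SSE curve.  Returns the chosen k and the full curve.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2:
        raise CartographyError("k_range must start at >= 2")
    if ks[-1] > max(2, em_filtered.n_genes // 10):
        ks = [k for k in ks if k <= max(2, em_filtered.n_genes // 10)] or [2]
    if replicates < 1:
        raise CartographyError("replicates must be >= 1")
    x = _zscore_profiles(em_filtered)
    sses = []
    for i, k in enumerate(ks):
        km = KMeans(
            n_clusters=k, init="random", n_init=replicates,
            random_state=(seed + 7 * i) % (2**31 - 1),
        ).fit(x)
        sses.append(float(km.inertia_))
    curve = pd.DataFrame({"k": ks, "sse": sses})
    if any(sses[i + 1] > sses[i] for i in range(len(sses) - 1)):
        logger.warning("SSE scree not monotone decreasing; increase replicates")
    if len(ks) < 3:
        return ks[0], curve
    d2 = [sses[i - 1] - 2 * sses[i] + sses[i + 1] for i in range(1, len(ks) - 1)]
    chosen = ks[1 + int(np.argmax(d2))]
    logger.info("scree elbow at k=%d", chosen)
    return chosen, curve


def kmeans_partition(
    em_filtered: ExpressionMatrix,
    k: int,
    replicates: int = 100,
    seed: int = 0,
) -> CommunityPartition:
    """Replicated k-means on z-scored profiles; winning replicate = lowest SSE.

    Deterministic given the seed.  If the winning replicate leaves a cluster
    empty the fit is re-drawn (up to 10 times) before erroring.
    """
    if k < 2:
        raise CartographyError(f"k must be >= 2, got {k}")
    if k > em_filtered.n_genes:
        raise CartographyError("k exceeds number of genes")
    x = _zscore_profiles(em_filtered)
    for attempt in range(10):
        km = KMeans(
            n_clusters=k, init="random", n_init=replicates,
            random_state=(seed + 101 * attempt) % (2**31 - 1),
        ).fit(x)
        if len(set(km.labels_)) == k:
            break
    else:
        raise CartographyError(f"k-means left an empty cluster after 10 redraws (k={k})")
    # relabel to contiguous ids, ordered by first appearance
    remap: dict[int, int] = {}
    for lab in km.labels_:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    assignment = {
        g: remap[lab] for g, lab in zip(em_filtered.gene_ids, km.labels_)
    }
    return CommunityPartition(assignment, k, float(km.inertia_), replicates)


# ---------------------------------------------------------------------------
# node statistics
# ---------------------------------------------------------------------------

def _check_cover(net: CorrelationNetwork, part: CommunityPartition) -> None:
    missing = [n for n in net.nodes if n not in part.assignment]
    if missing:
        raise CartographyError(f"partition misses network node {missing[0]!r}")


def internal_degrees(net: CorrelationNetwork, part: CommunityPartition) -> pd.Series:
    """Number of each node's neighbours inside its own module."""
    _check_cover(net, part)
    kappa = {
        n: sum(
            1 for nb in net.graph.neighbors(n)
            if part.assignment[nb] == part.assignment[n]
        )
        for n in net.nodes
    }
    return pd.Series(kappa, dtype=float)


def within_module_degree_z(
    net: CorrelationNetwork, part: CommunityPartition
) -> pd.Series:
    """Within-module degree z-score Zg (population sd; flat module -> 0)."""
    kappa = internal_degrees(net, part)
    modules = pd.Series({n: part.assignment[n] for n in net.nodes})
    zg = pd.Series(0.0, index=kappa.index)
    for _, idx in kappa.groupby(modules).groups.items():
        vals = kappa.loc[idx]
        sd = float(vals.std(ddof=0))
        if sd > 0:
            zg.loc[idx] = (vals - vals.mean()) / sd
    return zg


def clusterphobic_coefficient(
    net: CorrelationNetwork, part: CommunityPartition
) -> pd.Series:
    """Kpi = 1 - (internal degree / total degree)^2; isolated nodes get 0."""
    kappa = internal_degrees(net, part)
    total = pd.Series({n: float(net.graph.degree(n)) for n in net.nodes})
    kpi = pd.Series(0.0, index=kappa.index)
    pos = total > 0
    kpi[pos] = 1.0 - (kappa[pos] / total[pos]) ** 2
    return kpi


def average_neighbor_correlation(net: CorrelationNetwork) -> pd.Series:
    """APCC: mean signed edge weight over each node's neighbours (NaN when
    the node has no neighbours)."""
    apcc = {}
    for n in net.nodes:
        ws = [net.graph.edges[n, nb]["weight"] for nb in net.graph.neighbors(n)]
        apcc[n] = float(np.mean(ws)) if ws else np.nan
    return pd.Series(apcc, dtype=float)


def classify_nodes(
    zg: pd.Series,
    kpi: pd.Series,
    apcc: pd.Series,
    thresholds: CartographyThresholds | None = None,
    module: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the per-node cartography table.

    Hub class from APCC sign/magnitude (fight club < 0 <= date < party
    boundary <= party); region from the Zg-Kpi plane; ``is_switch`` marks R4
    fight club hubs; ``is_strong_hub`` flags Zg above the strict hub cut.
    Nodes without neighbours (APCC undefined) get hub class ``none`` and are
    excluded from switch calling.
    """
    th = thresholds or CartographyThresholds()
    idx = zg.index
    out = pd.DataFrame({"zg": zg, "kpi": kpi.reindex(idx), "apcc": apcc.reindex(idx)})
    if module is not None:
        out.insert(0, "module", module.reindex(idx).astype(int))

    def hub_class(a: float) -> str:
        if np.isnan(a):
            return "none"
        if a < 0:
            return "fight_club"
        return "party" if a >= th.apcc_party else "date"

    def region(z: float, kp: float) -> str:
        if z < th.zg_hub:
            b1, b2, b3 = th.kpi_nonhub_bounds
            if kp <= b1:
                return "R1"
            if kp <= b2:
                return "R2"
            return "R3" if kp <= b3 else "R4"
        b1, b2 = th.kpi_hub_bounds
        if kp <= b1:
            return "R5"
        return "R6" if kp <= b2 else "R7"

    out["hub_class"] = [hub_class(a) for a in out["apcc"]]
    out["region"] = [region(z, kp) for z, kp in zip(out["zg"], out["kpi"])]
    out["is_switch"] = (
        (out["region"] == "R4")
        & (out["apcc"] < 0)
        & out["apcc"].notna()
    )
    out["is_strong_hub"] = out["zg"] > th.zg_strong_hub
    return out


def compute_cartography(
    net: CorrelationNetwork,
    part: CommunityPartition,
    thresholds: CartographyThresholds | None = None,
) -> pd.DataFrame:
    """Full cartography table (module, Zg, Kpi, APCC, class, region, flags)."""
    zg = within_module_degree_z(net, part)
    kpi = clusterphobic_coefficient(net, part)
    apcc = average_neighbor_correlation(net)
    module = pd.Series({n: part.assignment[n] for n in net.nodes})
    return classify_nodes(zg, kpi, apcc, thresholds, module=module)


def extract_switch_genes(
    cart: pd.DataFrame, condition_label: str, provenance: str = ""
) -> SwitchGeneSet:
    """Collect the called switch genes, sorted lexicographically."""
    genes = sorted(cart.index[cart["is_switch"]])
    if not genes:
        logger.warning("no switch genes called for %s", condition_label)
    else:
        logger.info("%d switch genes called for %s", len(genes), condition_label)
    return SwitchGeneSet(condition_label, genes, provenance)
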