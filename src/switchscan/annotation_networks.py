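"""Database-agnostic downstream annotation of switch genes.

All four analyses take user-supplied snapshots (PPI edge lists, GMT gene-set
collections, TF->target and chemical->gene tables) rather than bundling any
database:

* a Steiner-style minimum connected PPI subnetwork around the switch genes,
* hypergeometric over-representation of gene sets (Totals/Hits reporting),
* regulator ranking by query-target degree and betweenness, with a Venn
  consensus across sources,
* chemical ranking by the number of distinct query genes each compound hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .cross_condition import VennResult, venn_decompose
from .deg_filter import benjamini_hochberg
from .expr_io import GeneSetCollection, InteractionTable

logger = logging.getLogger("switchscan")


class AnnotationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# minimum connected subnetwork
# ---------------------------------------------------------------------------

def minimum_connected_subnetwork(
    ppi: InteractionTable, seeds: set[str]
) -> tuple[nx.Graph, set[str]]:
    """Heuristic minimum connected PPI subnetwork containing the seeds.

    Takes the PPI component holding the most seeds, unions the pairwise
    shortest paths between its seeds, then iteratively prunes non-seed leaves.
    Returns the connected subgraph and the set of seeds that were excluded
    (absent from the PPI or stranded in other components).
    """
    g = ppi.to_networkx()
    if g.is_directed():
        g = g.to_undirected()
    present = set(seeds) & set(g.nodes)
    if not present:
        raise AnnotationError("no seed gene is present in the PPI network")
    components = sorted(
        nx.connected_components(g),
        key=lambda c: (-len(c & present), min(c)),
    )
    comp = components[0]
    kept_seeds = sorted(comp & present)
    excluded = set(seeds) - set(kept_seeds)
    if excluded:
        logger.warning("%d seeds excluded (absent or in other PPI components)",
                       len(excluded))

    nodes: set[str] = set(kept_seeds)
    sub = g.subgraph(comp)
    for a, b in combinations(kept_seeds, 2):
        nodes.update(nx.shortest_path(sub, a, b))
    result = g.subgraph(nodes).copy()
    # prune connector dead-ends that serve no seed
    while True:
        leaves = [n for n in result.nodes
                  if result.degree(n) <= 1 and n not in present]
        if not leaves:
            break
        result.remove_nodes_from(leaves)
    return result, excluded


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------

def ora_hypergeometric(
    query: set[str], gsc: GeneSetCollection, universe: set[str]
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each gene set.

    Sets are intersected with the universe before testing (sets left empty are
    skipped); ``total`` is the set size within the universe, ``hits`` the
    overlap with the query, p = P(X >= hits) for a hypergeometric draw of
    ``|query|`` from ``|universe|``; q is BH across tested sets.  Rows are
    sorted by ascending p (ties by name).
    """
    query, universe = set(query), set(universe)
    if not universe or not query:
        raise AnnotationError("query and universe must be non-empty")
    if not query <= universe:
        raise AnnotationError(
            f"query genes outside the universe: {sorted(query - universe)[:5]}"
        )
    rows = []
    for name, gene_set in sorted(gsc):
        members = gene_set.genes & universe
        if not members:
            continue
        hits = len(members & query)
        p = float(stats.hypergeom.sf(hits - 1, len(universe), len(members), len(query)))
        rows.append((name, len(members), hits, min(p, 1.0)))
    if not rows:
        raise AnnotationError("no gene set overlaps the universe")
    df = pd.DataFrame(rows, columns=["set_name", "total", "hits", "p"])
    df["q"] = benjamini_hochberg(df["p"].to_numpy())
    return df.sort_values(["p", "set_name"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# regulator ranking
# ---------------------------------------------------------------------------

def rank_regulators(
    tf_edges: InteractionTable, query: set[str], source: str = ""
) -> pd.DataFrame:
    """Rank regulators of the query genes by degree and betweenness.

    The TF->target table is restricted to targets inside the query; degree is
    the number of distinct query targets; betweenness is computed on the
    resulting bipartite regulator-gene graph (undirected view).  Regulators
    with no query target are omitted.
    """
    if not tf_edges.directed:
        raise AnnotationError("regulator table must be directed (TF -> target)")
    targets: dict[str, set[str]] = {}
    for tf, gene, _ in tf_edges.edges:
        if gene in query:
            targets.setdefault(tf, set()).add(gene)
    if not targets:
        return pd.DataFrame(columns=["regulator", "degree", "betweenness", "source"])
    g = nx.Graph()
    for tf, genes in targets.items():
        for gene in genes:
            g.add_edge(tf, gene)
    bc = nx.betweenness_centrality(g, normalized=True)
    df = pd.DataFrame(
        {
            "regulator": list(targets),
            "degree": [len(targets[tf]) for tf in targets],
            "betweenness": [bc[tf] for tf in targets],
            "source": source,
        }
    )
    return (
        df.sort_values(["degree", "betweenness", "regulator"],
                       ascending=[False, False, True])
        .reset_index(drop=True)
    )


def consensus_regulators(rankings: dict[str, pd.DataFrame]) -> VennResult:
    """Venn consensus of regulator names across >= 2 sources.

    ``rankings`` maps a source tag to a ``rank_regulators`` frame (duplicate
    tags are impossible by construction of the dict; passing a list of
    (tag, frame) pairs with repeated tags raises).
    """
    if isinstance(rankings, (list, tuple)):
        tags = [t for t, _ in rankings]
        if len(set(tags)) != len(tags):
            raise AnnotationError(f"duplicate source tags: {tags}")
        rankings = dict(rankings)
    if len(rankings) < 2:
        raise AnnotationError("need rankings from >= 2 sources")
    return venn_decompose(
        {tag: set(df["regulator"]) for tag, df in rankings.items()}
    )


# ---------------------------------------------------------------------------
# chemical ranking
# ---------------------------------------------------------------------------

def rank_chemicals(
    chem_edges: InteractionTable, query: set[str], min_degree: int = 4
) -> pd.DataFrame:
    """Rank chemicals by the number of distinct query genes they interact with.

    Only chemicals reaching ``min_degree`` query genes are returned, sorted by
    degree descending with alphabetical tie-break; the associated genes are
    listed per chemical.
    """
    genes_by_chem: dict[str, set[str]] = {}
    for chem, gene, _ in chem_edges.edges:
        if gene in query:
            genes_by_chem.setdefault(chem, set()).add(gene)
    rows = [
        (chem, len(genes), ",".join(sorted(genes)))
        for chem, genes in genes_by_chem.items()
        if len(genes) >= min_degree
    ]
    df = pd.DataFrame(rows, columns=["chemical", "degree", "genes"])
    return (
        df.sort_values(["degree", "chemical"], ascending=[False, True])
        .reset_index(drop=True)
    )
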