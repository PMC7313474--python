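"""Cross-condition comparison of switch-gene sets.

Two views: an exact Venn decomposition of named sets (which genes are shared
between which dementias) and a biclustered ordering of the switch-gene
expression matrix (genes and samples co-clustered on correlation distance)
for heat-map rendering.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .cartography import SwitchGeneSet
from .expr_io import ExpressionMatrix


class CrossConditionError(ValueError):
    pass


@dataclass
class VennResult:
    """Exclusive region decomposition of named sets.

    ``regions`` maps each non-empty combination of labels (as a frozenset) to
    the sorted genes belonging to exactly those sets.  Regions are disjoint
    and their sizes sum to the union size.
    """

    labels: tuple[str, ...]
    regions: dict[frozenset[str], list[str]]

    @property
    def counts(self) -> dict[frozenset[str], int]:
        return {k: len(v) for k, v in self.regions.items()}

    def region(self, *labels: str) -> list[str]:
        """Genes in exactly the given labels (and no others)."""
        return self.regions.get(frozenset(labels), [])

    def intersection(self, *labels: str) -> list[str]:
        """Genes in all the given labels, regardless of the others."""
        want = frozenset(labels)
        out: set[str] = set()
        for key, genes in self.regions.items():
            if want <= key:
                out.update(genes)
        return sorted(out)

    @property
    def union_size(self) -> int:
        return sum(self.counts.values())


def venn_decompose(named_sets: dict[str, set[str]]) -> VennResult:
    """Exclusive Venn regions over arbitrarily many named sets."""
    if len(named_sets) < 2:
        raise CrossConditionError("need >= 2 named sets")
    labels = tuple(named_sets)
    regions: dict[frozenset[str], list[str]] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(set(named_sets[c]) for c in combo))
            outside = set.union(
                set(), *(set(named_sets[c]) for c in labels if c not in combo)
            )
            regions[frozenset(combo)] = sorted(inside - outside)
    return VennResult(labels, regions)


def intersect_switch_sets(sets: list[SwitchGeneSet]) -> VennResult:
    """Venn decomposition of per-condition switch-gene sets."""
    labels = [s.condition for s in sets]
    if len(set(labels)) != len(labels):
        raise CrossConditionError(f"duplicate condition labels: {labels}")
    return venn_decompose({s.condition: set(s.genes) for s in sets})


# ---------------------------------------------------------------------------
# biclustering
# ---------------------------------------------------------------------------

@dataclass
class BiclusterResult:
    """Row/column orders and merge trees for the switch-gene heat map."""

    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    matrix: pd.DataFrame  # per-gene z-scored values, original (sorted) axes


def _corr_distance(x: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance between rows; constant rows are treated
    as uncorrelated (distance 1) rather than undefined."""
    sd = x.std(axis=1)
    c = np.corrcoef(x)
    c = np.where(np.isfinite(c), c, 0.0)
    c[np.ix_(sd == 0, sd == 0)] = 0.0
    np.fill_diagonal(c, 1.0)
    d = np.clip(1.0 - c, 0.0, 2.0)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def bicluster_switch_expression(
    em: ExpressionMatrix, switch: SwitchGeneSet
) -> BiclusterResult:
    """Bicluster switch-gene expression for heat-map rendering.

    Rows (genes) are z-scored, then rows and columns are hierarchically
    clustered with average linkage on 1 - Pearson distance.  Inputs are
    pre-sorted by id so the leaf order is deterministic and invariant to the
    caller's row order.
    """
    genes = sorted(switch.genes)
    if len(genes) < 2:
        raise CrossConditionError("need >= 2 switch genes to bicluster")
    sub = em.subset_genes(genes)
    cols = sorted(sub.sample_ids)
    x = sub.data[cols].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    if (sd == 0).any():
        raise CrossConditionError("constant switch-gene profile cannot be z-scored")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]

    row_link = hierarchy.linkage(_corr_distance(z), method="average")
    col_link = hierarchy.linkage(_corr_distance(z.T), method="average")
    row_order = [genes[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [cols[i] for i in hierarchy.leaves_list(col_link)]
    return BiclusterResult(
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_link,
        col_linkage=col_link,
        matrix=pd.DataFrame(z, index=genes, columns=cols),
    )
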