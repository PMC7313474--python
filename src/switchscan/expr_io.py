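"""Readers and writers for the pipeline's file formats.

Expression matrices arrive as rectangular TSV tables (genes in rows, samples
in columns) or in the GEO series-matrix text dialect, where ``!``-prefixed
metadata lines wrap the same table.  Gene sets use GMT, interactions a 2-3
column edge TSV.  Everything downstream operates on log2 intensities, so the
reader forces the scale via an explicit flag rather than guessing.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("switchscan")

CONDITIONS = ("case", "control")

#: rows with more than this fraction of missing cells are dropped outright
MAX_MISSING_FRACTION = 0.20


class ExpressionInputError(ValueError):
    """Malformed expression table or inconsistent sample labels."""


@dataclass
class ExpressionMatrix:
    """Log2 gene x sample intensity table with case/control labels.

    Parameters
    ----------
    data:
        DataFrame of log2 intensities, index = gene ids, columns = sample ids.
    condition:
        Mapping sample id -> ``"case"`` or ``"control"`` covering every column.
    n_imputed:
        Number of cells filled by per-row mean imputation at load time.
    """

    data: pd.DataFrame
    condition: dict[str, str]
    n_imputed: int = 0

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ExpressionInputError(f"duplicate gene id {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ExpressionInputError(f"duplicate sample id {dup!r}")
        missing = [s for s in self.data.columns if s not in self.condition]
        if missing:
            raise ExpressionInputError(
                f"sample {missing[0]!r} has no condition label"
            )
        bad = {
            s: c
            for s, c in self.condition.items()
            if s in self.data.columns and c not in CONDITIONS
        }
        if bad:
            s, c = next(iter(bad.items()))
            raise ExpressionInputError(
                f"sample {s!r} has condition {c!r}; expected one of {CONDITIONS}"
            )
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ExpressionInputError("non-finite values after missing-value handling")
        # keep only labels for columns actually present
        self.condition = {s: self.condition[s] for s in self.data.columns}

    # -- accessors -------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.data.columns if self.condition[s] == condition]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes]
        absent = set(genes) - set(self.data.index)
        if absent:
            raise ExpressionInputError(f"genes not in matrix: {sorted(absent)[:5]}")
        return ExpressionMatrix(self.data.loc[genes].copy(), dict(self.condition))

    def require_differential_design(self) -> None:
        """At least 2 case and 2 control samples; needed for any group test."""
        for cond in CONDITIONS:
            n = len(self.samples_of(cond))
            if n < 2:
                raise ExpressionInputError(
                    f"condition {cond!r} has {n} samples; >=2 required"
                )


@dataclass
class GeneSet:
    description: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    """Named gene sets loaded from a GMT file."""

    sets: dict[str, GeneSet]

    def __post_init__(self) -> None:
        empty = [n for n, s in self.sets.items() if not s.genes]
        if empty:
            raise ValueError(f"empty gene set {empty[0]!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class InteractionTable:
    """Edge list for PPI / TF->target / chemical->gene interactions.

    Undirected tables store canonicalised (sorted) pairs; duplicates are
    collapsed keeping the first relation tag; self-loops are dropped at load.
    """

    edges: list[tuple[str, str, str]]
    directed: bool

    def __post_init__(self) -> None:
        if any(a == b for a, b, _ in self.edges):
            raise ValueError("self-loop present after load")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        for a, b, tag in self.edges:
            g.add_edge(a, b, relation=tag)
        return g


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (sample_id, case|control) into a label mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "condition"],
                     dtype=str, comment="!")
    return dict(zip(df["sample"].str.strip(), df["condition"].str.strip().str.lower()))


def _strip_series_matrix(text: str) -> str:
    """Drop GEO series-matrix metadata: '!'-prefixed and blank lines."""
    lines = [ln for ln in text.splitlines()
             if ln.strip() and not ln.lstrip().startswith("!")]
    return "\n".join(lines)


def read_expression_table(
    path: str | Path,
    label_map: Mapping[str, str],
    already_log2: bool = True,
) -> ExpressionMatrix:
    """Read a genes x samples TSV (plain or GEO series-matrix dialect).

    Non-numeric cells are treated as missing; rows with more than 20% missing
    are dropped, the rest are mean-imputed per row and the imputed-cell count
    is recorded on the result.  When ``already_log2`` is false every value is
    transformed by ``log2(x + 1)``.
    """
    text = Path(path).read_text()
    df = pd.read_csv(io.StringIO(_strip_series_matrix(text)), sep="\t",
                     index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip().str.strip('"')
    df.columns = df.columns.astype(str).str.strip().str.strip('"')
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ExpressionInputError(f"duplicate sample id {dup!r}")
    unlabeled = [s for s in df.columns if s not in label_map]
    if unlabeled:
        raise ExpressionInputError(
            f"sample {unlabeled[0]!r} present in the table but missing from labels"
        )

    vals = df.apply(lambda col: pd.to_numeric(col.str.strip('"'), errors="coerce"))
    frac_missing = vals.isna().mean(axis=1)
    dropped = int((frac_missing > MAX_MISSING_FRACTION).sum())
    if dropped:
        logger.warning("dropping %d rows with >%.0f%% missing cells",
                       dropped, 100 * MAX_MISSING_FRACTION)
    vals = vals.loc[frac_missing <= MAX_MISSING_FRACTION]
    n_imputed = int(vals.isna().to_numpy().sum())
    if n_imputed:
        row_means = vals.mean(axis=1)
        vals = vals.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
        logger.info("imputed %d missing cells by per-row means", n_imputed)
    if not already_log2:
        if (vals.to_numpy() < 0).any():
            raise ExpressionInputError("negative values on a declared linear scale")
        vals = np.log2(vals + 1.0)

    labels = {s: str(label_map[s]).lower() for s in vals.columns}
    return ExpressionMatrix(vals.astype(float), labels, n_imputed=n_imputed)


def write_expression_table(
    em: ExpressionMatrix,
    path: str | Path,
    labels_path: str | Path | None = None,
) -> None:
    """Write the matrix as TSV (values at 6 decimals) and optionally labels."""
    em.data.to_csv(path, sep="\t", float_format="%.6f", index_label="gene")
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            for s in em.sample_ids:
                fh.write(f"{s}\t{em.condition[s]}\n")


def collapse_probes(
    em: ExpressionMatrix, probe_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse probe-level rows to genes, keeping the probe with the highest
    mean intensity when several probes map to the same gene; unmapped probes
    are dropped."""
    mapped = [p for p in em.gene_ids if p in probe_to_gene]
    if not mapped:
        raise ExpressionInputError("no probe maps to a gene symbol")
    means = em.data.loc[mapped].mean(axis=1)
    best: dict[str, str] = {}
    for probe in mapped:
        gene = probe_to_gene[probe]
        if gene not in best or means[probe] > means[best[gene]]:
            best[gene] = probe
    genes = sorted(best)
    out = em.data.loc[[best[g] for g in genes]].copy()
    out.index = pd.Index(genes, name=em.data.index.name)
    return ExpressionMatrix(out, dict(em.condition))


# ---------------------------------------------------------------------------
# gene sets and interaction tables
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (set name, description, members per tab-separated line).

    Lines with fewer than 3 fields are skipped with a warning; members are
    de-duplicated; duplicate set names are merged by union.
    """
    sets: dict[str, GeneSet] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            logger.warning("GMT line %d has <3 fields; skipped", i)
            continue
        name, desc = fields[0].strip(), fields[1].strip()
        members = frozenset(m.strip() for m in fields[2:] if m.strip())
        if not members:
            logger.warning("GMT line %d has no members; skipped", i)
            continue
        if name in sets:
            logger.warning("duplicate GMT set %r merged by union", name)
            members = members | sets[name].genes
        sets[name] = GeneSet(desc, members)
    if not sets:
        raise ValueError(f"no valid gene sets in {path}")
    return GeneSetCollection(sets)


def read_interaction_table(path: str | Path, directed: bool) -> InteractionTable:
    """Read a 2-3 column edge TSV; extra columns are ignored.

    Self-loops are removed and duplicate edges collapsed; undirected tables
    canonicalise each pair so (A,B) and (B,A) collapse to one edge.
    """
    seen: dict[tuple[str, str], str] = {}
    order: list[tuple[str, str]] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = [f.strip() for f in line.rstrip("\n").split("\t")]
        if len(fields) < 2 or not fields[0] or not fields[1]:
            logger.warning("interaction line %d malformed; skipped", i)
            continue
        a, b = fields[0], fields[1]
        tag = fields[2] if len(fields) >= 3 else ""
        if a == b:
            continue
        key = (a, b) if directed else (min(a, b), max(a, b))
        if key not in seen:
            seen[key] = tag
            order.append(key)
    if not seen:
        raise ValueError(f"no valid edges in {path}")
    return InteractionTable([(a, b, seen[(a, b)]) for a, b in order], directed)
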