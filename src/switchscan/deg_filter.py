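"""Pre-processing and differential filtering with an adaptive fold-change cut.

Unexpressed genes are dropped first (mean below a low quantile, or zero
variance).  Per-gene statistics are a Welch t-test on log2 intensities with
Benjamini-Hochberg FDR.  The linear fold-change threshold is then scanned over
the 1.5-4x band and the smallest value retaining between ``target_low`` and
``target_high`` significant genes is selected, so the downstream network is
built on a 1000-2000 gene core regardless of cohort size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expr_io import ExpressionMatrix

logger = logging.getLogger("switchscan")


class FilterError(ValueError):
    pass


@dataclass
class FilterConfig:
    """Thresholds for pre-filtering and differential selection.

    fc_min/fc_max bound the linear fold-change scan; target_low/target_high
    is the desired retained-gene band; alpha is the FDR level applied to the
    BH-adjusted q-values; expression_floor_quantile sets the "slightly
    expressed" floor as a quantile of per-gene mean intensity.
    """

    fc_min: float = 1.5
    fc_max: float = 4.0
    target_low: int = 1000
    target_high: int = 2000
    alpha: float = 0.05
    expression_floor_quantile: float = 0.10
    grid_step: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.fc_min <= self.fc_max:
            raise FilterError(f"need 0 < fc_min <= fc_max, got {self.fc_min}, {self.fc_max}")
        if not self.target_low < self.target_high:
            raise FilterError("target_low must be < target_high")
        if not 0 < self.alpha < 1:
            raise FilterError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 <= self.expression_floor_quantile < 1:
            raise FilterError("expression_floor_quantile must be in [0,1)")


@dataclass
class ThresholdSelection:
    """Chosen linear fold-change threshold plus the scan it came from."""

    threshold: float
    retained_count: int
    in_band: bool
    scan: pd.DataFrame  # columns: threshold, retained


def prefilter_expression(em: ExpressionMatrix, cfg: FilterConfig | None = None) -> ExpressionMatrix:
    """Remove unexpressed / flat genes before testing.

    A gene is dropped when its mean intensity falls below the configured
    quantile of all gene means, or when its variance across samples is zero.
    """
    cfg = cfg or FilterConfig()
    means = em.data.mean(axis=1)
    floor = means.quantile(cfg.expression_floor_quantile)
    variances = em.data.var(axis=1, ddof=0)
    keep = (means >= floor) & (variances > 0)
    if not keep.any():
        raise FilterError("no gene survives the expression pre-filter")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("pre-filter removed %d of %d genes (floor %.3f)",
                    dropped, em.n_genes, floor)
    return ExpressionMatrix(em.data.loc[keep].copy(), dict(em.condition))


def differential_stats(em: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene differential statistics on log2 values.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (mean case
    minus mean control), ``p`` (two-sided Welch t-test), ``q`` (BH-adjusted)
    and ``retained`` (False until a threshold is applied).
    """
    em.require_differential_design()
    case = em.data[em.samples_of("case")].to_numpy()
    ctrl = em.data[em.samples_of("control")].to_numpy()
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance-in-both-groups ties
    q = benjamini_hochberg(p)
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "q": q, "retained": False}, index=em.data.index
    )


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, clipped to [0,1])."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1] if p.size else p


def _retained_mask(ds: pd.DataFrame, threshold: float, alpha: float) -> pd.Series:
    linear_fc = np.power(2.0, ds["log2fc"].abs())
    return (linear_fc >= threshold) & (ds["q"] < alpha)


def select_fold_change_threshold(
    ds: pd.DataFrame, cfg: FilterConfig | None = None
) -> ThresholdSelection:
    """Scan linear fold-change thresholds and pick the smallest one whose
    retained count lands in the target band.

    The scan runs over ``[fc_min, fc_max]`` on a ``grid_step`` grid, counting
    genes with ``|linear FC| >= t`` and ``q < alpha``.  If no grid point lands
    in ``[target_low, target_high]`` the threshold whose count is closest to
    the band is returned (ties break toward the lower threshold) and the
    result is flagged out-of-band.
    """
    cfg = cfg or FilterConfig()
    if int((ds["q"] < cfg.alpha).sum()) == 0:
        raise FilterError(
            f"no gene significant at FDR {cfg.alpha}; relax alpha or check inputs"
        )
    n_steps = int(round((cfg.fc_max - cfg.fc_min) / cfg.grid_step))
    grid = np.round(cfg.fc_min + cfg.grid_step * np.arange(n_steps + 1), 10)
    counts = np.array(
        [int(_retained_mask(ds, t, cfg.alpha).sum()) for t in grid]
    )
    scan = pd.DataFrame({"threshold": grid, "retained": counts})
    in_band = (counts >= cfg.target_low) & (counts <= cfg.target_high)
    if in_band.any():
        i = int(np.argmax(in_band))  # smallest threshold in band
        return ThresholdSelection(float(grid[i]), int(counts[i]), True, scan)
    dist = np.where(
        counts < cfg.target_low, cfg.target_low - counts, counts - cfg.target_high
    )
    i = int(np.argmin(dist))  # argmin takes the first = lowest threshold on ties
    logger.warning(
        "no threshold lands in the %d-%d gene band; closest is %.2f (%d genes)",
        cfg.target_low, cfg.target_high, grid[i], counts[i],
    )
    return ThresholdSelection(float(grid[i]), int(counts[i]), False, scan)


def apply_filter(
    em: ExpressionMatrix,
    ds: pd.DataFrame,
    threshold: float,
    alpha: float = 0.05,
) -> ExpressionMatrix:
    """Restrict the matrix to genes passing the differential filter.

    Updates ``ds["retained"]`` in place so the stats table stays consistent
    with the returned matrix.
    """
    if threshold < 1:
        raise FilterError(f"linear threshold must be >= 1, got {threshold}")
    mask = _retained_mask(ds, threshold, alpha)
    ds["retained"] = mask
    genes = list(ds.index[mask])
    if len(genes) < 10:
        raise FilterError(
            f"only {len(genes)} genes retained; network would be degenerate"
        )
    return em.subset_genes(genes)


def fold_change_histogram(
    ds: pd.DataFrame, threshold: float, alpha: float = 0.05, bins: int = 50
) -> pd.DataFrame:
    """Binned log2 fold-change distribution split into retained/eliminated
    counts (the red/grey bars of the selection histogram).  Bin counts sum to
    the number of tested genes."""
    retained = _retained_mask(ds, threshold, alpha)
    edges = np.histogram_bin_edges(ds["log2fc"], bins=bins)
    total, _ = np.histogram(ds["log2fc"], bins=edges)
    kept, _ = np.histogram(ds.loc[retained, "log2fc"], bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "total": total,
            "retained": kept,
            "eliminated": total - kept,
        }
    )
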