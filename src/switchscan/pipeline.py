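"""End-to-end switch-gene pipeline driven by a single config.

Stage order: filter -> network -> cartography -> robustness -> compare ->
enrich.  Every threshold that affects output lives in :class:`PipelineConfig`
(validated before any compute), is echoed into the run manifest together with
input digests and per-stage counts, and a manifest can be re-run to reproduce
every stage output byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation_networks import minimum_connected_subnetwork, ora_hypergeometric
from .cartography import (
    CartographyThresholds,
    SwitchGeneSet,
    choose_k_scree,
    compute_cartography,
    extract_switch_genes,
    kmeans_partition,
)
from .coexpr_network import CorrelationNetwork, build_network, correlation_matrix
from .cross_condition import intersect_switch_sets
from .deg_filter import (
    FilterConfig,
    apply_filter,
    differential_stats,
    fold_change_histogram,
    prefilter_expression,
    select_fold_change_threshold,
)
from .expr_io import (
    ExpressionMatrix,
    read_expression_table,
    read_gmt,
    read_interaction_table,
    read_labels,
    write_expression_table,
)
from .robustness import removal_curves
from .synthetic_data import SyntheticSpec, generate_expression

logger = logging.getLogger("switchscan")

STAGES = ("filter", "network", "cartography", "robustness", "compare", "enrich")


class ConfigError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Input is either an expression TSV + labels TSV or an inline synthetic
    spec.  Defaults mirror the published procedure: fold-change band 1.5-4
    targeting 1000-2000 genes, FDR 0.05, switch rule Zg < 2.5 & Kpi > 0.8 &
    APCC < 0, strong-hub flag at Zg > 5.
    """

    condition_label: str = "case"
    expr_path: str | None = None
    labels_path: str | None = None
    already_log2: bool = True
    synthetic: dict | None = None

    # filter stage
    fc_min: float = 1.5
    fc_max: float = 4.0
    target_low: int = 1000
    target_high: int = 2000
    alpha: float = 0.05
    expression_floor_quantile: float = 0.10

    # network stage
    pcc_floor: float = 0.6
    alpha_edge: float = 0.05
    corr_scope: str = "all"

    # cartography stage
    k: int | str = "auto"
    k_min: int = 2
    k_max: int = 10
    replicates: int = 100
    scree_replicates: int = 20
    zg_hub: float = 2.5
    kpi_switch: float = 0.8
    apcc_party: float = 0.5
    zg_strong_hub: float = 5.0

    # robustness stage
    robustness_enabled: bool = False
    removal_repeats: int = 10
    removal_max_fraction: float = 0.5

    # compare / enrich stages (optional inputs)
    compare_sets: dict[str, str] = field(default_factory=dict)  # label -> txt path
    gmt_path: str | None = None
    ppi_path: str | None = None

    seed: int = 17
    out_dir: str | None = None

    def validate(self) -> None:
        if (self.expr_path is None) == (self.synthetic is None):
            raise ConfigError("provide exactly one of expr_path or synthetic")
        if self.expr_path is not None and self.labels_path is None:
            raise ConfigError("labels_path is required with expr_path")
        self.filter_config()  # raises on bad fc band / alpha / quantile
        if not 0 <= self.pcc_floor <= 1:
            raise ConfigError(f"pcc_floor must be in [0,1], got {self.pcc_floor}")
        if not 0 < self.alpha_edge < 1:
            raise ConfigError(f"alpha_edge must be in (0,1), got {self.alpha_edge}")
        if self.corr_scope not in ("all", "case_only"):
            raise ConfigError(f"corr_scope must be all|case_only, got {self.corr_scope}")
        if self.k != "auto" and (not isinstance(self.k, int) or self.k < 2):
            raise ConfigError(f"k must be 'auto' or an int >= 2, got {self.k}")
        if not 2 <= self.k_min <= self.k_max:
            raise ConfigError("need 2 <= k_min <= k_max")
        if self.replicates < 1 or self.scree_replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if not 0 < self.removal_max_fraction <= 1:
            raise ConfigError("removal_max_fraction must be in (0,1]")
        if self.zg_hub <= 0 or not 0 < self.kpi_switch < 1:
            raise ConfigError("bad cartography thresholds")

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            fc_min=self.fc_min, fc_max=self.fc_max,
            target_low=self.target_low, target_high=self.target_high,
            alpha=self.alpha,
            expression_floor_quantile=self.expression_floor_quantile,
        )

    def cartography_thresholds(self) -> CartographyThresholds:
        return CartographyThresholds(
            zg_hub=self.zg_hub, kpi_switch=self.kpi_switch,
            apcc_party=self.apcc_party, zg_strong_hub=self.zg_strong_hub,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PipelineResult:
    switch_set: SwitchGeneSet
    diffstats: pd.DataFrame
    filtered: ExpressionMatrix
    network: CorrelationNetwork
    partition_k: int
    cartography: pd.DataFrame
    manifest: dict
    robustness: pd.DataFrame | None = None
    venn: object | None = None
    enrichment: pd.DataFrame | None = None


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_switch_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in order; any stage failure aborts with its name."""
    config.validate()
    manifest: dict = {
        "package": "switchscan",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {},
        "stages": {},
        "counts": {},
    }
    for key in ("expr_path", "labels_path", "gmt_path", "ppi_path"):
        p = getattr(config, key)
        if p:
            manifest["inputs"][key] = {"path": str(p), "sha256_16": _digest(p)}

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        if out_dir is not None:
            df.to_csv(out_dir / name, sep="\t", float_format="%.6g", **kw)

    # ---- stage: filter --------------------------------------------------
    try:
        if config.synthetic is not None:
            spec = SyntheticSpec(**{**config.synthetic, "seed": config.seed})
            em, _truth = generate_expression(spec)
        else:
            labels = read_labels(config.labels_path)
            em = read_expression_table(config.expr_path, labels, config.already_log2)
        manifest["counts"]["input_genes"] = em.n_genes
        manifest["counts"]["samples"] = em.n_samples
        fcfg = config.filter_config()
        em_pre = prefilter_expression(em, fcfg)
        ds = differential_stats(em_pre)
        sel = select_fold_change_threshold(ds, fcfg)
        em_filt = apply_filter(em_pre, ds, sel.threshold, fcfg.alpha)
        manifest["counts"].update(
            prefiltered_genes=em_pre.n_genes,
            fc_threshold=sel.threshold,
            threshold_in_band=sel.in_band,
            retained_genes=em_filt.n_genes,
        )
        manifest["stages"]["filter"] = "run"
        save(ds, "diffstats.tsv", index_label="gene")
        save(fold_change_histogram(ds, sel.threshold, fcfg.alpha), "fc_histogram.tsv",
             index=False)
        if out_dir:
            write_expression_table(em_filt, out_dir / "filtered_expr.tsv",
                                   out_dir / "labels.tsv")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineStageError("filter", exc) from exc

    # ---- stage: network --------------------------------------------------
    try:
        scope_n = (
            em_filt.n_samples if config.corr_scope == "all"
            else len(em_filt.samples_of("case"))
        )
        corr = correlation_matrix(em_filt, config.corr_scope)
        net = build_network(corr, config.pcc_floor, config.alpha_edge, scope_n)
        manifest["counts"]["network_edges"] = net.n_edges
        manifest["counts"]["negative_edges"] = int(
            sum(1 for *_, d in net.graph.edges(data=True) if d["weight"] < 0)
        )
        manifest["stages"]["network"] = "run"
        save(net.to_edge_frame(), "network.tsv", index=False)
    except Exception as exc:
        raise PipelineStageError("network", exc) from exc

    # ---- stage: cartography ----------------------------------------------
    try:
        if config.k == "auto":
            k, scree = choose_k_scree(
                em_filt, range(config.k_min, config.k_max + 1),
                config.scree_replicates, config.seed,
            )
            save(scree, "scree.tsv", index=False)
        else:
            k = int(config.k)
        part = kmeans_partition(em_filt, k, config.replicates, config.seed)
        cart = compute_cartography(net, part, config.cartography_thresholds())
        switch = extract_switch_genes(
            cart, config.condition_label,
            provenance=f"switchscan {__version__} seed={config.seed}",
        )
        manifest["counts"].update(
            k=k, kmeans_sse=part.sse, n_switch=len(switch),
            n_fight_club=int((cart["hub_class"] == "fight_club").sum()),
            n_strong_hub=int(cart["is_strong_hub"].sum()),
        )
        manifest["stages"]["cartography"] = "run"
        save(cart, "cartography.tsv", index_label="gene")
        if out_dir:
            (out_dir / "switch_genes.txt").write_text(
                "".join(g + "\n" for g in switch.genes)
            )
    except Exception as exc:
        raise PipelineStageError("cartography", exc) from exc

    # ---- stage: robustness (optional) -------------------------------------
    curves = None
    try:
        if config.robustness_enabled:
            grid = np.arange(0.0, config.removal_max_fraction + 1e-9, 0.05)
            curves = removal_curves(
                net, cart, fraction_grid=grid,
                repeats=config.removal_repeats, seed=config.seed,
            )
            manifest["stages"]["robustness"] = "run"
            save(curves, "robustness.tsv", index=False)
        else:
            manifest["stages"]["robustness"] = "skipped (disabled)"
    except Exception as exc:
        raise PipelineStageError("robustness", exc) from exc

    # ---- stage: compare (optional) -----------------------------------------
    venn = None
    try:
        if config.compare_sets:
            sets = [switch]
            for label, path in config.compare_sets.items():
                genes = sorted(
                    {ln.strip() for ln in Path(path).read_text().splitlines()
                     if ln.strip()}
                )
                sets.append(SwitchGeneSet(label, genes, provenance=str(path)))
            venn = intersect_switch_sets(sets)
            manifest["stages"]["compare"] = "run"
            if out_dir:
                payload = {
                    "&".join(sorted(k)): v for k, v in venn.regions.items()
                }
                (out_dir / "venn.json").write_text(json.dumps(payload, indent=2))
        else:
            manifest["stages"]["compare"] = "skipped (no comparison sets)"
    except Exception as exc:
        raise PipelineStageError("compare", exc) from exc

    # ---- stage: enrich (optional) ------------------------------------------
    enrichment = None
    try:
        if config.gmt_path and len(switch) > 0:
            gsc = read_gmt(config.gmt_path)
            if config.ppi_path:
                ppi = read_interaction_table(config.ppi_path, directed=False)
                subnet, _excluded = minimum_connected_subnetwork(
                    ppi, set(switch.genes)
                )
                universe = set(subnet.nodes)
                query = set(switch.genes) & universe
            else:
                universe = set(em.gene_ids)
                query = set(switch.genes)
            if query:
                enrichment = ora_hypergeometric(query, gsc, universe)
                save(enrichment, "enrichment.tsv", index=False)
                manifest["stages"]["enrich"] = "run"
            else:
                manifest["stages"]["enrich"] = "skipped (no query in universe)"
        else:
            manifest["stages"]["enrich"] = "skipped (no gene sets)"
    except Exception as exc:
        raise PipelineStageError("enrich", exc) from exc

    if out_dir:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(
        switch_set=switch, diffstats=ds, filtered=em_filt, network=net,
        partition_k=k, cartography=cart, manifest=manifest,
        robustness=curves, venn=venn, enrichment=enrichment,
    )


def run_from_manifest(manifest_path: str | Path, out_dir: str | Path | None = None
                      ) -> PipelineResult:
    """Re-run a pipeline from a manifest's config echo (bit-identical stages)."""
    manifest = json.loads(Path(manifest_path).read_text())
    cfg = PipelineConfig.from_dict(manifest["config"])
    if out_dir is not None:
        cfg.out_dir = str(out_dir)
    return run_switch_pipeline(cfg)
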