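"""Synthetic two-condition expression matrices with planted switch genes.

The generator is a latent-factor model: each module m has a per-sample factor
f_m ~ N(0,1) and a module gene is w*f_m + noise, which gives a closed-form
expected within-module correlation rho = w^2 / (w^2 + sigma^2).  Planted
switch genes load *negatively* on two different module factors, so their
expression anti-correlates with both anchor modules and their network
neighbours fall mostly outside whichever community k-means puts them in —
exactly the fight-club/R4 signature the pipeline is supposed to recover.
Case samples additionally receive per-module fold-change shifts inside the
1.5-4x band so the differential filter retains the structured genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .cartography import SwitchGeneSet
from .expr_io import ExpressionMatrix, write_expression_table

logger = logging.getLogger("switchscan")

FC_BAND_LOG2 = (math.log2(1.5), 2.0)  # permitted per-gene condition effects


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Generative parameters for a planted-module expression matrix.

    rho_within is the target Pearson correlation between genes of the same
    module; rho_switch the (negative) target correlation between a planted
    switch gene and its two anchor modules; log2fc_signal the per-module
    case/control shift on the log2 scale (must stay inside the 1.5-4x linear
    band); noise_sd the i.i.d. Gaussian noise level on log2 intensities.
    """

    n_modules: int = 4
    genes_per_module: int = 300
    n_switch: int = 20
    n_background: int = 15
    n_case: int = 20
    n_control: int = 20
    rho_within: float = 0.7
    rho_switch: float = -0.5
    log2fc_signal: float = 1.0
    noise_sd: float = 0.3
    baseline_range: tuple[float, float] = (6.0, 10.0)
    background_baseline_range: tuple[float, float] = (4.0, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rho_within < 1:
            raise SyntheticError(f"rho_within must be in (0,1), got {self.rho_within}")
        if not -1 < self.rho_switch < 0:
            raise SyntheticError(f"rho_switch must be in (-1,0), got {self.rho_switch}")
        for name in ("n_modules", "genes_per_module", "n_switch", "n_background",
                     "n_case", "n_control"):
            if getattr(self, name) < 1:
                raise SyntheticError(f"{name} must be >= 1")
        if self.n_modules < 2:
            raise SyntheticError("need >= 2 modules to anchor switch genes")
        if not FC_BAND_LOG2[0] <= self.log2fc_signal <= FC_BAND_LOG2[1]:
            raise SyntheticError(
                f"log2fc_signal must lie in [{FC_BAND_LOG2[0]:.3f}, {FC_BAND_LOG2[1]:.1f}]"
            )
        if self.noise_sd <= 0:
            raise SyntheticError("noise_sd must be > 0")
        # feasibility of the anti-correlation target given the within-module
        # loading: |rho_switch| < sqrt(rho_within / 2)
        if abs(self.rho_switch) >= math.sqrt(self.rho_within / 2):
            raise SyntheticError(
                "infeasible rho_switch: |rho_switch| must be < sqrt(rho_within/2) "
                f"= {math.sqrt(self.rho_within / 2):.3f}"
            )


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the matrix."""

    module: dict[str, int]          # gene -> module id (0 = unstructured)
    switch_genes: frozenset[str]
    anchors: dict[str, tuple[int, int]]  # switch gene -> anchor modules
    log2fc: dict[str, float]        # true per-gene condition effect

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.module)
        return pd.DataFrame(
            {
                "module": [self.module[g] for g in genes],
                "is_switch": [g in self.switch_genes for g in genes],
                "true_log2fc": [self.log2fc[g] for g in genes],
            },
            index=pd.Index(genes, name="gene"),
        )


def generate_expression(spec: SyntheticSpec) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one synthetic two-condition log2 expression matrix.

    Deterministic given ``spec.seed``: the same spec reproduces the matrix
    byte-identically.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_case + spec.n_control
    sigma = spec.noise_sd
    # module loading from the target within-module correlation
    w = sigma * math.sqrt(spec.rho_within / (1.0 - spec.rho_within))
    # switch loading: gene = -v (f_a + f_b)/sqrt(2) + noise anti-correlates
    # with module-a genes at rho = -(v w / sqrt(2)) / sqrt((v^2+s^2)(w^2+s^2))
    u = math.sqrt(2.0) * abs(spec.rho_switch) / math.sqrt(spec.rho_within)
    v = sigma * u / math.sqrt(1.0 - u * u)

    factors = rng.standard_normal((spec.n_modules, n_samples))
    case_mask = np.concatenate(
        [np.ones(spec.n_case), np.zeros(spec.n_control)]
    )
    samples = [f"case{i + 1:03d}" for i in range(spec.n_case)] + [
        f"ctrl{i + 1:03d}" for i in range(spec.n_control)
    ]
    condition = {s: ("case" if s.startswith("case") else "control") for s in samples}

    rows: list[np.ndarray] = []
    genes: list[str] = []
    module_of: dict[str, int] = {}
    log2fc: dict[str, float] = {}

    def effect_magnitude() -> float:
        jitter = rng.uniform(0.9, 1.1) * spec.log2fc_signal
        return float(np.clip(jitter, FC_BAND_LOG2[0], FC_BAND_LOG2[1]))

    # module genes: shared factor + noise + baseline + condition shift
    for m in range(spec.n_modules):
        sign = 1.0 if m % 2 == 0 else -1.0  # alternate up/down modules
        for i in range(spec.genes_per_module):
            name = f"MOD{m + 1}_{i + 1:04d}"
            baseline = rng.uniform(*spec.baseline_range)
            eff = sign * effect_magnitude()
            profile = (
                baseline
                + w * factors[m]
                + sigma * rng.standard_normal(n_samples)
                + eff * case_mask
            )
            rows.append(profile)
            genes.append(name)
            module_of[name] = m + 1
            log2fc[name] = eff

    # planted switch genes: negative load on two anchor modules.  Anchors are
    # chosen among modules sharing the same condition-effect sign and the
    # switch gene shifts the opposite way, so the case/control effect
    # reinforces (never cancels) the planted anti-correlation.
    pair_cycle = [
        (a, b) for a, b in combinations(range(spec.n_modules), 2)
        if a % 2 == b % 2
    ] or list(combinations(range(spec.n_modules), 2))
    anchors: dict[str, tuple[int, int]] = {}
    switch_names = []
    for i in range(spec.n_switch):
        a, b = pair_cycle[i % len(pair_cycle)]
        name = f"SWITCH{i + 1:03d}"
        baseline = rng.uniform(*spec.baseline_range)
        anchor_sign = 1.0 if a % 2 == 0 else -1.0  # == b's sign when same-parity
        eff = -anchor_sign * effect_magnitude()
        profile = (
            baseline
            - v * (factors[a] + factors[b]) / math.sqrt(2.0)
            + sigma * rng.standard_normal(n_samples)
            + eff * case_mask
        )
        rows.append(profile)
        genes.append(name)
        module_of[name] = 0
        log2fc[name] = eff
        anchors[name] = (a + 1, b + 1)
        switch_names.append(name)

    # unstructured, weakly expressed background (what the pre-filter removes)
    total_sd = math.sqrt(w * w + sigma * sigma)
    for i in range(spec.n_background):
        name = f"BG{i + 1:03d}"
        baseline = rng.uniform(*spec.background_baseline_range)
        profile = baseline + total_sd * rng.standard_normal(n_samples)
        rows.append(profile)
        genes.append(name)
        module_of[name] = 0
        log2fc[name] = 0.0

    data = pd.DataFrame(np.vstack(rows), index=pd.Index(genes, name="gene"),
                        columns=samples)
    em = ExpressionMatrix(data, condition)
    truth = SyntheticTruth(module_of, frozenset(switch_names), anchors, log2fc)
    return em, truth


@dataclass
class RecoveryResult:
    precision: float  # NaN when nothing was called but something was planted
    recall: float
    n_called: int
    n_planted: int
    true_positives: int


def evaluate_recovery(truth: SyntheticTruth, called: SwitchGeneSet) -> RecoveryResult:
    """Precision/recall of a called switch set against the planted truth.

    Empty called + empty planted scores 1/1; empty called with a non-empty
    planted set has recall 0 and undefined (NaN) precision.
    """
    called_set = called.as_set()
    planted = truth.switch_genes
    tp = len(called_set & planted)
    if not called_set:
        precision = 1.0 if not planted else float("nan")
    else:
        precision = tp / len(called_set)
    recall = 1.0 if not planted else tp / len(planted)
    return RecoveryResult(precision, recall, len(called_set), len(planted), tp)


# ---------------------------------------------------------------------------
# fixture files for the downstream annotation stages
# ---------------------------------------------------------------------------

def write_fixture_files(out_dir: str | Path, spec: SyntheticSpec) -> dict[str, Path]:
    """Materialise one synthetic dataset plus toy GMT/PPI/TF/chemical tables.

    The annotation fixtures are derived from the planted truth so every
    pipeline stage has a file to chew on: a GMT with one set per planted
    module, a PPI chaining the switch genes through module genes, a TF table
    targeting switch genes and a CTD-style chemical table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    em, truth = generate_expression(spec)
    paths = {
        "expr": out / "expr.tsv",
        "labels": out / "labels.tsv",
        "truth": out / "truth.tsv",
        "gmt": out / "sets.gmt",
        "ppi": out / "ppi.tsv",
        "tf": out / "tf.tsv",
        "chem": out / "chem.tsv",
    }
    write_expression_table(em, paths["expr"], paths["labels"])
    truth.to_frame().to_csv(paths["truth"], sep="\t")

    modules: dict[int, list[str]] = {}
    for g, m in truth.module.items():
        if m > 0:
            modules.setdefault(m, []).append(g)
    with open(paths["gmt"], "w") as fh:
        for m in sorted(modules):
            members = "\t".join(sorted(modules[m])[:25])
            fh.write(f"MODULE_{m}\tplanted module {m}\t{members}\n")
        fh.write("SWITCH_SET\tplanted switch genes\t"
                 + "\t".join(sorted(truth.switch_genes)) + "\n")

    switch = sorted(truth.switch_genes)
    with open(paths["ppi"], "w") as fh:
        for s in switch:
            a, b = truth.anchors[s]
            fh.write(f"{s}\t{sorted(modules[a])[0]}\tppi\n")
            fh.write(f"{s}\t{sorted(modules[b])[0]}\tppi\n")
    with open(paths["tf"], "w") as fh:
        for i, s in enumerate(switch):
            fh.write(f"TF{i % 3 + 1}\t{s}\tbinds\n")
    with open(paths["chem"], "w") as fh:
        for s in switch[: max(4, len(switch) // 2)]:
            fh.write(f"compound_X\t{s}\ttargets\n")
        for s in switch[:2]:
            fh.write(f"compound_Y\t{s}\ttargets\n")
    return paths
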