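# Methods

## The statistic the package exists for

A *switch gene* is a node of a signed co-expression network that sits in
region R4 of the heat-cartography plane and anti-correlates with its
neighbourhood:

* **Zg < 2.5** — within-module degree z-score. For node *i* in module *m*
  with κᵢ neighbours inside *m*: Zg = (κᵢ − mean_m(κ)) / sd_m(κ), using the
  population standard deviation; a module whose internal degrees are all
  equal gives Zg = 0 for its members. A separate flag marks *strong hubs*
  (Zg > 5), which by definition can never be switch genes.
* **Kπ > 0.8** — clusterphobic coefficient 1 − (κᵢ/kᵢ)² with kᵢ the total
  degree; close to 1 when most links leave the node's own community.
  Isolated nodes get Kπ = 0 and are excluded from switch calling.
* **APCC < 0** — mean signed Pearson correlation between the node's
  expression profile and those of its network neighbours. Nodes with
  negative APCC are *fight club hubs*; APCC in [0, 0.5) marks date hubs and
  APCC ≥ 0.5 party hubs (the 0.5 split is a convention; "low" versus "high"
  positive co-expression is not quantified anywhere authoritative). Nodes
  without neighbours have undefined APCC and no hub class.

Region boundaries on the Zg–Kπ plane follow the classical cartography
convention: non-hubs (Zg < 2.5) split at Kπ = 0.05 / 0.62 / 0.8 into R1–R4,
hubs at Kπ = 0.30 / 0.75 into R5–R7. Only the 0.8 switch boundary and the
2.5 / 5 Zg cuts are prescribed by the method itself; the remaining
breakpoints are reporting conventions and are configurable.

## Pipeline stages and defaults

**Pre-filter.** Genes whose mean log2 intensity falls below the 10th
percentile of all gene means, or whose variance is zero, are dropped.
"Slightly expressed" is inherently vague; a quantile floor adapts to any
intensity scale. Note a quantile floor removes a fixed share of genes even
when all are well expressed — see Limitations.

**Differential filter.** log2 fold change is the difference of group means on
the log2 scale; significance is a two-sided Welch t-test (unequal variances
are the norm between patient groups) with Benjamini–Hochberg correction at
α = 0.05. The linear fold-change threshold is scanned over [1.5, 4] in steps
of 0.05; the smallest threshold retaining 1000–2000 significant genes is
selected. If no grid point lands in the band the closest one is used and the
run is flagged; the warning matters, because all network-level defaults
assume a network of roughly that size. Moderated tests (limma-style) were
deliberately not used to keep the stage self-contained and transparent.

**Network.** Pairwise Pearson correlation across all samples (cases and
controls; `corr_scope="case_only"` is available). An edge requires
|PCC| ≥ 0.6 (closed rule at the boundary) *and* BH-adjusted correlation
p < 0.05 (t-transform of r with n−2 df). Both knobs land in the run manifest
because the edge rule is the least standardised part of any such pipeline.
At the 1000–2000 gene scale the 0.6 floor yields connected, moderately dense
networks; with few samples the significance rule becomes the binding
constraint, with many samples the floor does.

**Communities.** k-means on per-gene z-scored profiles (Euclidean distance),
replicated from fresh random centroids; the replicate with the lowest SSE
wins. k is chosen from the scree curve of min-SSE over k = 2…10 by the
largest second forward difference (the discrete elbow). Scree inspection is
a manual step in interactive use; the elbow rule automates it and `k` can be
fixed explicitly. The scree scan uses 20 replicates per k and the final
partition 100: the scan only needs the elbow's location, the final partition
needs the tightest SSE minimum. All k-means runs are seeded and
deterministic; an empty cluster in the winning replicate triggers a re-draw
(at most 10) before erroring.

**Robustness.** The diagnostic is the unweighted average shortest path
length (APL) of the largest connected component, recomputed while removing
growing fractions of one hub class in seeded random order and averaged over
repeats. Components of one node score 0. Removal fractions are fractions of
the class size; for a fair targeted-versus-random comparison the random
curve accepts `match_class`, which draws the *same number* of nodes
network-wide that the targeted curve removes from the class — the standard
attack-versus-failure design. Without matching, "random at fraction f"
removes f·N_total nodes against the targeted curve's f·N_class, and the
comparison only measures class size. APL is computed by C-level BFS on the
sparse adjacency matrix, which keeps repeated evaluation on dense
correlation networks tractable.

**Cross-condition.** Venn decomposition is exact over arbitrarily many named
sets (exclusive regions; sizes sum to the union). Biclustering z-scores each
gene, then clusters genes and samples by average linkage on 1 − Pearson
distance; inputs are sorted by identifier before linkage so leaf orders are
deterministic and invariant to caller ordering. Constant profiles cannot be
z-scored and are rejected; constant columns are treated as uncorrelated
(distance 1).

**Annotation.** The minimum connected PPI subnetwork is a Steiner-style
heuristic (optimal Steiner trees are NP-hard): take the PPI component
holding the most seeds, union the pairwise shortest paths between its seeds,
then prune non-seed leaves; stranded seeds are reported as excluded.
Over-representation uses the upper-tail hypergeometric test
P(X ≥ hits) with BH across sets, reporting each set's size within the
universe (Totals) and overlap with the query (Hits); when a PPI is supplied
the universe is the minimum-network node set, otherwise all genes of the
expression matrix. Regulator ranking counts distinct query targets per
regulator (degree) and computes betweenness on the undirected bipartite
regulator–target graph; consensus across sources reuses the Venn
decomposition. Chemicals are ranked by distinct query genes touched, with a
degree ≥ 4 default cut and alphabetical tie-break.

## The synthetic-data generator

Each module *m* has a latent per-sample factor f_m ~ N(0,1); a module gene is
baseline + w·f_m + ε with ε ~ N(0, σ²), so the expected within-module
correlation is ρ = w²/(w² + σ²) and w is solved from the requested
`rho_within`. A planted switch gene loads *negatively* on two anchor modules,
−v·(f_a + f_b)/√2 + ε, with v solved so its expected correlation to anchor
genes equals `rho_switch`; the target is feasible only when
|rho_switch| < √(rho_within/2), and infeasible requests raise immediately.

Condition effects: each module shifts its case samples by ±`log2fc_signal`
(alternating sign across modules, ±10% per-gene jitter, clipped to the
1.5–4× linear band). Anchor pairs are chosen among modules sharing the same
effect sign and the switch gene shifts the *opposite* way: a condition shift
shared between a switch gene and its anchor module adds +e²/4 to their
covariance and can cancel the planted anti-correlation, whereas the opposed
shift reinforces it. Baselines are drawn per gene from U(6, 10) (typical
log2 microarray intensities); `n_background` unstructured genes get U(4, 6)
baselines and emulate the weakly expressed pool the pre-filter exists to
remove.

What the generator does **not** emulate: probe-level artifacts, saturation,
batch effects, outlier samples, heavy-tailed noise, correlated noise between
modules, or realistic library-size structure. Passing tests on this
generator demonstrate that the pipeline recovers the planted topology under
the stated model — not that any particular biological dataset will yield
stable switch genes.

A caveat that matters when interpreting recovery rates: with a shared
case/control shift, correlation across *all* samples contains a
condition-driven component (two genes shifted the same way gain +e²/4
covariance). At the default settings this component is what makes
same-module genes cluster tightly; at low noise it can also wire
condition-driven edges *between* modules. The targeted-attack experiment
therefore uses a higher noise level (σ = 0.6), where the closed forms put
the cross-module correlation near 0.17 — far below the 0.6 edge floor — so
inter-module connectivity genuinely flows through the planted connectors.

## Reference experiment sizes

The recovery experiment uses the generator at 4 modules × 300 genes,
20 switch genes, 15 background genes, 20+20 samples, ρ_within 0.7,
ρ_switch −0.5, log2 effect 1.0, σ 0.3, five seeds, full default pipeline.
The targeted-attack experiment uses 3 modules × 80 genes, 10 switch genes,
30+30 samples, σ 0.6, twenty seeds, comparing fight-club removal against the
size-matched random control at 30% class removal. Both sizes give stable
statistics at interactive runtimes.

## Numerical conventions and degenerate inputs

* BH adjustment is the standard step-up with cumulative-minimum
  monotonisation, clipped to [0, 1]; q ≥ p always.
* Correlation p-values use the t-transform; |r| = 1 maps to p = 0.
* Welch tests on two zero-variance equal-mean groups return p = 1.
* Zg of a zero-sd module is 0; Kπ of an isolated node is 0; APCC of an
  isolated node is undefined (NaN) and excludes it from hub classes and
  switch calls.
* Threshold scans break ties toward the lower threshold; chemical and
  regulator rankings break ties alphabetically; biclustering pre-sorts by
  identifier.
* Probe collapse keeps the probe with the highest mean intensity.
  Expression cells that fail to parse are mean-imputed per row, and rows
  with more than 20% missing cells are dropped.
* Input scale is never guessed: the reader applies log2(x+1) only when told
  the data are linear.

## Known limitations

* The edge rule (0.6 floor + FDR 0.05) and the APCC party/date split (0.5)
  are conventions, not estimated quantities; cohorts with very different
  sample sizes may warrant different floors, which is why both are manifest
  entries.
* The quantile pre-filter always removes ~10% of genes, including some
  genuinely expressed ones; on the synthetic cohorts this is the dominant
  source of missed planted switch genes.
* k-means with Euclidean distance on z-scored profiles assumes roughly
  spherical module shapes; elongated or nested co-expression structures may
  split or merge.
* The scree elbow is a heuristic; when the SSE curve is nearly linear the
  chosen k is weakly determined and should be overridden manually.
* The minimum connected subnetwork is a heuristic upper approximation of the
  Steiner tree; it is guaranteed connected and no larger than the
  shortest-path union, not minimal.
* Correlations over all samples mix co-regulation with condition effects;
  `corr_scope="case_only"` isolates within-condition co-expression at the
  cost of half the sample size.
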