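# Methods

## Scope and model

`cernanet` implements the standard ceRNA screening procedure for two-group
lncRNA+mRNA expression arrays: differentially expressed lncRNAs and mRNAs are
linked through shared miRNAs taken from interaction catalogues, the resulting
tripartite graph is analyzed with three centralities, and hub regulators are
the nodes simultaneously top-ranked in all three. The pipeline assumes:

* expression values are already on a log2 scale, normalized, and annotated
  with gene symbols and biotypes (probe-level re-annotation is out of scope;
  duplicate symbols are collapsed by the per-sample mean, the least
  informative rule when the probe→symbol mapping is many-to-one);
* miRNAs are not profiled — they enter only through the catalogues, so no
  expression filter is ever applied to them;
* interaction catalogues are plain files; no live database queries.

## Differential expression

Per-gene pooled two-sample variances `s²_g` with residual df `d = n₁+n₂−2`
are modeled hierarchically: `σ²_g ~ scaled-inv-χ²(d₀, s₀²)`. The
hyperparameters are estimated by matching the first two moments of
`log s²_g`: with `e_g = log s²_g − ψ(d/2) + log(d/2)`,

    var(e) − ψ′(d/2) = ψ′(d₀/2) · 1/2⁻¹   (solved by Newton inversion of ψ′)
    log s₀² = mean(e) + ψ(d₀/2) − log(d₀/2)

where ψ, ψ′ are the digamma/trigamma functions. When the observed spread of
log-variances does not exceed what sampling alone explains, `d₀ = ∞` and the
statistic reduces to a z-like test against the pooled prior variance; a
single-gene matrix provides nothing to pool and falls back to the ordinary
two-sample t (df `d`). Genes with zero variance and zero mean difference get
`t = 0, p = 1`. The moderated t uses the posterior variance
`s̃²_g = (d₀s₀² + d s²_g)/(d₀+d)` and df `d₀+d`.

Variances are moderated jointly across lncRNAs and mRNAs: both biotypes come
off the same array and share the noise model, and pooling across all genes
stabilizes the prior estimate.

BH adjustment is the exact step-up rule (`adj_(i) = min_{j≥i} p_(j)·m/j`,
clipped at 1). DE calls use strict inequalities (`|log2FC| > 1`,
`p_adj < 0.05`) — a gene exactly on a threshold is not called; a relaxed
(`≥`/`≤`) mode is available because conventions differ between studies.

## Interactions

The consensus miRNA–mRNA set is the plain three-way intersection of the
catalogues — a pair must be predicted by all three sources. An optional
negative-correlation filter for ceRNA pairs exists but is **off by default**:
it requires expression for both endpoints of a pair, which the targeted
platform cannot supply for miRNAs. miRNA identifiers are normalized
case-insensitively, preserving the `hsa-` prefix.

## Network topology

The graph is undirected and simple; edges exist only between lncRNA–miRNA
and miRNA–mRNA. Assembly prunes miRNAs that do not bridge both sides (they
cannot mediate competition), then drops isolated nodes; consequently every
miRNA in the final network has degree ≥ 2.

Centrality conventions (all values reproducible against brute-force
shortest-path oracles in the test suite):

* **degree** — raw edge count, reported as an integer;
* **closeness** — component-scoped with whole-graph scaling: for node v in a
  component of size c within a graph of n nodes,
  `(c−1)/Σ_{u∈comp} d(v,u) · (c−1)/(n−1)`. This is the convention common
  network-analysis tools use for disconnected graphs and keeps values in
  [0,1]; harmonic closeness is available via `mode="harmonic"` for users who
  prefer it;
* **betweenness** — Brandes' dependency accumulation: equally short paths
  share credit fractionally, endpoints are excluded, and raw values are
  divided by `(n−1)(n−2)/2` unordered pairs.

Class differences are assessed with the Kruskal–Wallis rank test with tie
correction; with all observations tied the 0/0 case is resolved to H = 0
(no separation). P-values come from the χ² approximation with (classes−1) df.

**Hub rule.** For each centrality the top k nodes are taken with competition
ranking: every node tied with the k-th value is included, which makes the
call independent of input order at the cost of occasionally exceeding k.
Hubs are the three-way intersection. All node classes are eligible; in
practice hub sets contain lncRNAs and miRNAs, since mRNAs sit on the
periphery of the tripartite topology.

## Over-representation

One-sided hypergeometric upper tail `P[X ≥ k]` for a query of K genes against
a term annotating n of N universe genes (the universe defaults to all genes
on the array — the measurable background — and is configurable). The default
filter is raw `P < 0.05`, matching common ORA practice for this analysis
style; the BH-adjusted P is reported in the output for users who prefer FDR
filtering but deliberately not used as the default cutoff. Terms are flat
gene sets: no ontology-graph propagation.

## Synthetic data

The generator emulates the targeted study design: 10 case + 10 control
samples; 250 lncRNAs + 600 mRNAs on the array and 40 miRNAs in the
catalogues; 35% of genes planted with signed effects of 2 log2 units;
per-gene variances drawn from inverse-gamma(shape 4, scale 1.5) — mean
variance 0.5, i.e. typical per-gene SD ≈ 0.7 on the log2 scale, a realistic
array noise level and the exact family the moderated-t prior assumes, which
makes hyperparameter recovery a meaningful test; three target catalogues in
which each true miRNA–mRNA pair appears independently with probability 0.9
(decoy pairs are capped at two catalogues, so the triple intersection at
full overlap equals the planted truth exactly); and 4 hub lncRNAs with 25
miRNA partners each against a background mean of 2.4 partners
(`lnc_mi_prob = 0.06`). True miRNA–mRNA pairs arise with probability 0.04
(~24 targets per miRNA). Hub lncRNAs are always among the planted DE genes:
a hub that the DE screen removes cannot appear in the network, and the
planted hubs represent the disease-specific regulators the design assumes.

What the generator does **not** emulate: probe-level intensities and
re-annotation, array normalization artifacts, correlated noise between
genes, miRNA expression, catalogue-specific biases (sources are exchangeable
here), and annotation terms with real ontology structure. Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery under the stated model, not robustness to the full messiness of
real array data.

## Numerical choices

* Newton inversion of the trigamma function starts at `0.5 + 1/y` with
  asymptotic shortcuts for extreme arguments; convergence tolerance 1e-10.
* BH and centralities use stable sorts; all set-valued outputs are sorted
  before serialization, so a run is byte-reproducible from (config, seed).
* Each generator consumes an independent child stream of the master seed
  (`SeedSequence([seed, stage])`), so expression and interaction draws do
  not interfere.
* Problem sizes in the validation suite (graphs ≤ 30 nodes for oracle
  equivalence, 5000 genes for null calibration, the default synthetic study
  for end-to-end recovery) were chosen to make brute-force oracles exact and
  fast while leaving every statistical check well-powered.

## Known limitations

* The moderated-t calibration is exact under the hierarchical model; heavy
  departures (e.g. outlier variances) would call for the robustified prior
  fit, which is not implemented.
* The closeness convention on disconnected graphs is a choice; published
  centrality tables rarely state theirs, so cross-study comparisons of
  absolute closeness values need care.
* Raw-P enrichment filtering inflates the term-level false positive rate;
  the BH column is provided precisely so users can filter on it instead.
* With k = 40 and tie-inclusive ranking, hub sets can exceed 40 per metric
  when centralites tie, which is logged.
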