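# Methods

## The model

`reaxpot` interprets steady-state metabolomics through the lens of *reaction
rate potentials*. For a reaction with enzyme activity $[p]$, substrates $A_i$
and products $B_j$, the rate potential is modelled mass-action style as

$$r = k\,[p]\,\frac{\prod_i [A_i]^{m_i}}{\prod_j [B_j]^{m_j}}$$

where $k$ is the reaction-specific rate coefficient and $m \in \{1, 2\}$ is an
*approximate* stoichiometric exponent: 1 for a stoichiometric coefficient of
1, and 2 for any larger coefficient. The model assumes that at the reference
state the substrate/product ratio is balanced and that $k$ (the catalytic
nature of the enzyme) does not change between conditions; $k$ then cancels in
the ratio of test to reference states, and on the log scale

$$\log_2\mathrm{FC}(r) = \log_2\mathrm{FC}(p)
  + \sum_i m_i\,\log_2\mathrm{FC}(A_i)
  - \sum_j m_j\,\log_2\mathrm{FC}(B_j).$$

Only *measured* terms enter the sum; unmeasured substrates or products
contribute zero. A reaction is testable ("expressed") when it has at least one
measured substrate, one measured product, and a measured enzyme. A positive
$\log_2\mathrm{FC}(r)$ means the test state has accumulated substrate and/or
enzyme relative to product — the reaction would need to run faster to restore
the reference balance. Note what this is *not*: it is not a flux estimate. A
perturbation that raises flux while leaving the substrate/product ratio
untouched is invisible to the method, as is a pathway shifting uniformly in
one direction; isotope-tracing flux analysis would be needed there.

Interpretation caveats worth keeping in mind: the sum treats the measured
fold-changes as exchangeable evidence, so one extreme metabolite can dominate
a reaction's score, and reversible reactions are scored in the as-written
direction only (re-scoring the reverse direction would merely negate the
value).

## Preprocessing

The pipeline order is fixed: half-missing filter → per-feature minimum
imputation → quantile normalization → enzyme aggregation (gene/protein
matrices) → $\log_2(x+1)$. The order is enforced by a state flag
(`raw → normalized → log2`) so stages cannot be silently reordered.

* **Filter:** features with more than half of their sample values missing are
  dropped (with $n$ samples, at most $\lfloor n/2\rfloor$ missing survive).
* **Imputation:** remaining missing values are read as below-detection-limit
  and replaced by the *per-feature* minimum observed value. The per-feature
  (rather than global) minimum avoids dragging high-abundance features toward
  the matrix floor.
* **Quantile normalization:** every sample is mapped onto the mean
  order-statistic distribution; ties receive the mean of the reference
  quantiles they span. It is applied by default and can be disabled
  (`quantile_normalize: false`) for platforms where it is inappropriate.
* **Enzyme activity:** per sample, an isoenzyme is as abundant as its
  scarcest measured subunit (complex stoichiometry is limited by the rarest
  part); isoenzyme activities add. Isoenzymes with no measured subunit are
  skipped rather than zeroed, and wholly unmeasured enzymes are absent.
  Aggregation runs on the normalized linear scale, *before* the log
  transform, because minima and sums do not commute with the logarithm.
* **PCA:** run on centered (not scaled) log2 data; gene/protein matrices use
  the top 10% most variable features, metabolite matrices all features.

When a reaction lists several enzymes, their aggregated activities are summed
per sample before the fold-change is taken — the same additivity rule used
for isoenzymes, lifted to the reaction level.

## Differential analysis

Metabolite fold-changes are group-mean differences on the log2 scale, tested
with an empirical-Bayes moderated t: per-feature pooled variances are shrunk
toward a scaled inverse-chi-square prior fitted across all features by
moment-matching on log variances (digamma/trigamma moments; the trigamma
inverse is solved by Newton iteration). p-values use a t distribution with
prior-augmented degrees of freedom and are Benjamini–Hochberg adjusted.
Features with exactly zero pooled variance get $p = 1$ rather than an error,
so degenerate synthetic inputs cannot crash the pipeline. A feature is called
significant when adjusted $p < 0.05$ *and* $|\log_2\mathrm{FC}| > 0.5$, both
strict. The implementation is cross-checked against the limma reference in
the test suite. The design is deliberately two-group only (reference vs
test) with no covariates, and the robust-regression variant some pipelines
use for larger replicate counts is intentionally not implemented.

## Bootstrap ranking score

Parametric errors for $\log_2\mathrm{FC}(r)$ would require a variance model
across heterogeneous slots, so significance is ranked against a resampling
null instead: for each reaction, 500 (default) null values are computed by
refilling each measured metabolite slot with a draw (uniform, with
replacement) from the pool of *all* measured metabolite fold-changes, and
the enzyme slot from the pool of all per-reaction enzyme fold-changes,
keeping the reaction's topology — its number of measured substrate/product
slots and their $m$ exponents. The ranking score is

$$s = \frac{1 + \#\{|\text{null}| \ge |\log_2\mathrm{FC}(r)|\}}{n_\text{boot} + 1}
  \in (0, 1],$$

the add-one correction being the standard permutation-p convention that
avoids exact zeros. Reactions with $s < 0.05$ and $|\log_2\mathrm{FC}(r)| >
0.5$ (strict) are significant. Each reaction draws from its own
deterministic substream (seed combined with a CRC of the reaction id), so
results are bit-reproducible and independent of processing order. On null
data the scores are approximately uniform (checked in the acceptance suite);
they are *ranking* scores against the dataset's own background, not
calibrated p-values.

## Pathway analysis and graphs

Over-representation uses the hypergeometric upper tail on pathway membership
intersected with the measured background (all network-mapped measured
metabolites, or all testable reactions), min 3 in-background members per
pathway, BH-adjusted; enrichment is reported at FDR < 0.05. The background is
the measured universe rather than the whole network because unmeasurable
members carry no information about the experiment.

Graphs are bipartite (compound and reaction nodes; substrate/product edges).
The pathway view shows one pathway's reactions and every measured compound
on them, significant or not. The global view seeds from significant
metabolites and reactions and expands one hop (configurable) — reactions
touching seed metabolites, then measured metabolites on any included
reaction. No currency-metabolite filtering is applied by default: highly
connected cofactors (ADP, orthophosphate, ...) are often exactly the
connective tissue worth seeing; an exclusion list can be supplied when they
drown the picture. Exports: GraphML, Cytoscape JSON (both lossless for node
and edge attributes), and a dependency-free interactive HTML page.

## Simulation benchmark

The generator emulates a two-group multiomics design over a synthetic
reaction network and doubles as the test-fixture factory.

**Network.** Default 2000 compounds, 3000 reactions, 1500 enzymes — KEGG-ish
scale at desk-scale runtime. Each reaction draws 1–3 substrates and 1–3
products (distinct compounds, $m = 2$ with probability 0.1) and one enzyme;
enzymes have 1–3 isoenzymes of 1–2 private subunit genes. Compound degree is
therefore roughly uniform (mean ≈ 6); real metabolic networks are heavy-tailed
(hub cofactors), which is the main structural idealization here.

**Data.** Per feature, a mean intensity $\mu \sim \Gamma(\text{shape},
\text{scale})$ (metabolites: 1.2/3000; genes: 0.8/800); replicates on the
log2 scale are $\mathcal{N}(\log_2(\mu+1) + \Delta,\ \sigma(\mu))$ with the
mean–variance decay $\sigma(\mu) = a\,e^{-b \log_2(\mu+1)} + c$, reflecting
that bright features are measured more precisely. Defaults: metabolites
$a=0.8, b=0.25, c=0.38$ (bright-feature SD ≈ 0.43 log2 units, CV ≈ 35% —
typical of untargeted-metabolomics biological replicates); genes $a=0.15,
b=0.25, c=0.02$ (RNA-seq-like precision; the resulting null per-reaction
enzyme fold-change SD is ≈ 0.05). The two noise scales were fixed once to
place the benchmark at a realistic operating point — a no-enzyme mean AUC
near 0.70 at metabolite effect 0.3 — and are not revisited; everything
downstream (monotonicity in both effect sizes, null calibration, strict
ordering and the margins of the integrated scorers) is an untuned
consequence. Matrices are emitted on the linear scale
($2^v - 1$, floored at 0) so every preprocessing stage is exercised.

**Planted truth.** 10% of reactions (half up, half down) are changed; for an
up-reaction the substrates and the enzyme's subunit genes get $+\Delta$ and
the products $-\Delta$ (mirrored for down), making the planted
$\log_2\mathrm{FC}(r)$ positive and maximal. A metabolite (or enzyme) pulled
in opposite directions by two changed reactions is reset to unchanged and
labelled null — changed reactions keep their labels, so conflicted
components are a genuine source of misses. The alternative all-concordant
convention (`concordant_products=True`) is implemented but cancels the
substrate/product signal almost entirely (AUC ≈ 0.53 at effect 0.3) and is
not the default. At effect 0 all effective labels are null; the originally
selected reactions are retained separately (`planted`) so null calibration
has a label set to rank against.

**Scoring.** Reactions are ranked by $|\log_2\mathrm{FC}(r)|$ — threshold-free,
hence ROC/AUC via the trapezoid rule — with the enzyme term included
(integrated) or forced to 0 (metabolite-only). The bootstrap is skipped in
the benchmark since AUC already integrates over thresholds.

**Problem sizes.** The headline benchmark (acceptance script and suite) uses
the default network with 20 seeded runs per condition; the monotonicity grid
and null calibration in the test suite use a 600-compound / 900-reaction
network with 20 runs per cell, sizes chosen to keep a full run at coffee-break
scale without changing any generative parameter.

## What passing the simulation does and does not show

The generator draws features independently given the network: no correlated
biology, no batch effects, no missingness mechanism (values are complete; the
filter/imputation stages are exercised by dedicated unit fixtures instead),
no fold-change compression from ionization nonlinearity (assumed corrected
upstream), uniform compound degrees, and pre-mapped identifiers. Passing the
benchmark therefore shows the estimator and its enzyme integration behave
correctly under the stated generative model — not that they overcome any of
those real-data pathologies.

## Numerical notes

* Quantile-normalization ties: mean of the spanned reference quantiles
  (preserves column sums; collapses all-tied columns to the reference mean).
* Variance-prior fit excludes zero variances; if the observed spread of log
  variances does not exceed the sampling expectation, the prior degrees of
  freedom are infinite and all features share the common variance.
* Bootstrap substreams come from `default_rng([seed, crc32(reaction_id)])`;
  scores are invariant to reaction order and bit-stable across runs.
* Equation parsing rejects polymer/generic terms ("n C00001"), duplicated
  compounds on one side, and compounds appearing on both sides (silent
  cancellation would change $\log_2\mathrm{FC}(r)$); `<=` equations are
  normalized by swapping sides and marked irreversible.
* `m` collapse is lossy by design: serialization prints coefficient 2 for any
  $m = 2$ slot, preserving exactly the information the model consumes.
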