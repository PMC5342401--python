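# Methods

This note documents the models, conventions and design choices behind
`leadnet`, in the order the pipeline runs them, followed by the synthetic
data model and known limitations.

## Network model and scoring

An interaction network is an undirected graph over case-normalised gene
symbols with one combined confidence score per edge, constrained to (0, 1].
STRING-style integer exports (0–1000) are divided by 1000 at load time; the
dialect is auto-detected (all scores > 1 ⇒ integer) and can be forced.
Duplicate unordered pairs collapse to the maximum score — conservative and
order-independent — and self-loops are dropped with a warning rather than an
error, since literature-derived edge tables occasionally contain them.

Confidence filtering keeps edges with `min ≤ s ≤ max`, inclusive at both
ends (the conventional reading of a quoted band such as "0.9–0.99"); the
node set is preserved so that genes with no in-band interactions appear as
isolated, zero-scoring nodes rather than vanishing. Seed expansion is plain
breadth-first search on the filtered graph: `steps = 1` (the default,
matching the one-shell "add interactors" idiom) adds direct partners;
seeds absent from the network are retained as isolated nodes with a warning,
because symbol lists routinely contain names missing from a network's
namespace.

Neither WNL nor TIS has a universally fixed formula in the leader-gene
literature; here both are the sum of incident-edge confidence scores — WNL on
the unit scale, TIS on the integer ×1000 scale with each edge rounded
half-away-from-zero (fixed, locale-independent). The two are deliberately
concordant; if the class maximising mean WNL ever differs from the one
maximising mean TIS, the result carries a discordance warning rather than an
error, since the leader definition cites both scores.

## Class formation and separation

Classes are formed by k-means on the one-dimensional WNL values. In 1-D the
optimal k-means partition is contiguous in sorted order, so the global
optimum is found exactly by dynamic programming over split points (O(k n²),
vectorised); the result is deterministic and needs no random restarts, which
is why the run seed never influences class assignment. `k` may be fixed or
chosen automatically over 2…min(6, #distinct values) by maximum mean
silhouette (computed in O(n log n) via prefix sums; singleton clusters score
0; ties prefer the smaller k). Clustering WNL (rather than TIS or both) is a
documented choice — the two scores are proportional up to rounding, so the
partitions coincide in practice.

Class separation is assessed on gene-level WNL values by classical one-way
fixed-effects ANOVA plus Tukey HSD over class pairs, at a quoted
significance of 0.001. Classes with fewer than two members carry no
within-class variance and are excluded from the F test with a warning. When
every class is internally constant but classes differ (common when a clean
module faces an all-isolated background), the F statistic is reported as
infinite with p = 0; the all-equal degenerate case returns F = 0, p = 1.
Leaders are the members of the class with the highest mean WNL.

## Degree-distribution fit

The degree distribution counts nodes per degree k ≥ 1, with isolated nodes
reported separately. The default fit regresses log10 N(k) on log10 k by
ordinary least squares over all observed degrees — no binning and no k_min
search, mirroring the Cytoscape NetworkAnalyzer convention, which is the
only convention that yields both an exponent and an R². The exponent is
reported as the positive magnitude b of N(k) ∝ k^(−b). A flat set of logged
points with zero residuals takes R² = 1 by convention. The discrete
maximum-likelihood exponent (zeta-normalised, k_min = 1, bounded search over
b ∈ (1, 12]) is implemented purely as an independent cross-check; it
produces no R² and is not used in the pipeline. At least two distinct
degrees are required; small filtered subnetworks in which every gene has the
same degree (e.g. a pure module clique) skip the fit with a warning.

## Ontology over-representation

Annotations are optional (gene, term) pairs; an optional child→parent edge
table supplies the ontology, which must be a DAG (a cycle aborts with one
member named). The true-path rule is applied before testing: every gene
annotated to a term is annotated to all ancestors, idempotently. Each term
with at least one study hit is tested with the exact upper-tail
hypergeometric probability P(X ≥ k) for X ~ Hypergeom(N, K, n); the
background defaults to all annotated genes (the "complete annotation"
convention) and must contain the study set when supplied explicitly.
Multiple testing uses Benjamini–Hochberg step-up q-values (monotone,
capped at 1, permutation-stable; via statsmodels), with Bonferroni available
by flag. Only over-representation is tested. Results are ordered by
(p, term id) so ties break deterministically.

## Assay quantifications

**2^-ΔΔCt (Livak).** Technical replicates are averaged per (sample, gene)
before any differencing — the standard usage when reactions are run in
triplicate. ΔCt = mean Ct(target) − mean Ct(reference) per sample;
ΔΔCt subtracts the calibrator group's mean ΔCt (untreated cells in vitro, or
normal mucosa for patient tissue); fold = 2^−ΔΔCt. Because folds are
multiplicative, the group summary is the geometric mean with dispersion
reported as the back-transformed SD of log2 folds (2^sd, a unitless
multiplicative factor ≥ 1). The calibrator group's geometric-mean fold is 1
by construction. Missing reference reactions abort with the offending sample
named; no amplification-efficiency correction is applied (pure Livak).

**Wound healing.** Ratio = initial / final cell-free area (pixels); > 1
means migration into the wound. A fully closed wound (final area 0) is
returned as an infinite ratio flagged `closed`, and the grouped statistics
drop non-finite values with a warning, so infinities never reach the ANOVA.

**AO/EB.** Live/apoptotic/necrotic fractions of the per-field count total;
they sum to 1 within 1e-12 by construction.

**DNA fragmentation.** Index = 1 − intact-band/total-lane intensity ∈ [0, 1];
higher means more degraded (apoptotic laddering).

**Statistics core.** Shapiro–Wilk is the decisive normality screen (gate
passes iff every group's p > α); the Kolmogorov–Smirnov statistic against a
normal with estimated parameters is reported as advisory only, with the
Lilliefors caveat logged, because the decision rule when both tests are run
is rarely stated. Zero-variance groups fail the gate with a defined
statistic. ANOVA is computed from sums of squares; Tukey HSD uses the
studentized range distribution with the Kramer standard error
`sqrt(MSW/2 · (1/n_i + 1/n_j))` for unbalanced groups. Significance flags are
decided against a cached critical value `q_{1−α}(k, df)` — mathematically
identical to `p_adj < α` but far cheaper, since evaluating the studentized
range survival function costs tens of milliseconds; `pvalues=False` skips
the survival-function call entirely for large null simulations. Assay
statistics are quoted at α = 0.05, network class separation at 0.001.

## Synthetic data model

The generators produce every input the pipeline reads, deterministically per
seed, each with a planted, recoverable target. They exercise contracts; they
do not imitate the human interactome or GO.

**Network.** Preferential attachment seeded with an initial clique of m + 1
nodes; each later node attaches m edges to distinct nodes with probability
proportional to degree, giving exactly `m(m+1)/2 + (n−m−1)m` edges (a closed
form the tests rely on) and an approximately power-law degree distribution.
Edge scores are Beta(a, b) rescaled to (0.5, 1]; the defaults a = 2, b = 3
put roughly 2–3 % of background edges inside a 0.9–0.99 band — a realistic
share of high-confidence interactions, and enough that the confidence filter
always has genuine work to do. The planted module occupies the earliest
(hub) nodes, wired pairwise at `planted_density` with score `planted_score`
(default: a 5-clique at 0.99 on a 100-node, m = 1 background). Module
boundary edges — backbone edges with exactly one planted endpoint — are
rescaled into (0.5, `boundary_score_max` = 0.9): the planted ground truth is
defined as the genes whose *high-confidence* interactions form the module,
so the module is separable by any confidence filter at or above the boundary
score, mirroring how a curated module's defining edges dominate its members'
high-confidence neighbourhoods. Background–background edges keep the full
support. `planted_leader_inputs(seed)` packages the canonical study design:
the network plus a 20-gene seed list (module members + 15 uniformly sampled
background genes), emulating a literature-derived starting list.

**Annotations.** Every (gene, term) pair present independently with
`base_prob`; one designated term additionally annotates a chosen gene set.

**Assays.** Four arms (control, metformin, CoCl₂, CoCl₂ + metformin), six
samples per arm, triplicate technical replicates. Reference Ct is
Normal(20, σ); target Ct is baseline + 2 (the calibrator ΔCt) − log2(fold) +
noise, so σ = 0 inverts exactly. Default folds (1, 1.5, 0.7, 2.5) model
target-gene induction strongest in the combined arm; wound final areas are
initial × effect × lognormal(0, 0.1) with effects (0.35, 0.55, 0.45, 0.75)
— treatment impairs closure; AO/EB counts are multinomial over 300 cells per
field with apoptotic probabilities (0.05, 0.12, 0.08, 0.40) and a necrotic
share fixed at 5 % of the apoptotic burden. These effect sizes are
illustrative magnitudes typical of such assays, chosen once and documented
here; no published raw measurements exist to calibrate against.

What passing tests on these generators shows: the pipeline's arithmetic,
contracts and error control are correct under known ground truth. What it
does not show: performance on real interactomes (evidence biases, hub
ascertainment, annotation incompleteness) or real qPCR data (efficiency
differences, batch effects), none of which the generators model.

## Numerical and degenerate-input conventions

- TIS rounding: half-away-from-zero on 1000 × score.
- k-means requires k ≤ #distinct values; all-equal scores cannot be split.
- Power-law fit: base-10 logs (affects the prefactor only); R² clipped to
  [0, 1]; zero-residual flat fits take R² = 1.
- Hypergeometric p-values are exact (scipy's survival function), validated
  against exhaustive draw enumeration for N ≤ 12 at 1e-12.
- Report CSVs are written at full float precision and round-trip to at least
  12 significant digits.
- Problem sizes in the calibration suites (200 oracle networks ≤ 50 nodes,
  100 planted-recovery runs, 1000 null enrichment studies, 5000 null ANOVA /
  Tukey replicates, 200 ΔΔCt seeds, 2000-node attachment networks) were
  chosen to give stable Monte-Carlo estimates at desk scale.

## Known limitations

- STRING's evidence-channel combination is not recomputed; combined scores
  are taken as given.
- No OBO parsing, evidence codes, or term-name resolution beyond the
  optional annotation column; the ontology input is a flat edge table.
- No goodness-of-fit p-value (KS bootstrap) or alternative heavy-tail model
  comparison for the degree distribution; with few distinct degrees the
  log–log R² is an unstable summary.
- No qPCR efficiency correction (Pfaffl); Livak assumes near-100 %
  efficiency for both genes.
- The ANOVA/Tukey stage assumes approximate normality and homoscedasticity;
  the normality gate flags but does not switch to non-parametric
  alternatives.
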