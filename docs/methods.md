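# Methods

This note documents the models, conventions and numerical choices behind
`oneironet`, in the spirit of a statistical package's methods appendix.

## Data model and harmonization

A dream report is an ordered list of lowercase noun tokens (compounds
hyphenated), labelled with a stress stratum: `increased`,
`unchanged_lowered`, or `unspecified` for reports whose respondent did
not answer the stress item. Token order encodes the dream's chronology
and duplicates are meaningful, so harmonization is length- and
order-preserving: the synonym map is applied first (so category rules
see canonical forms), then the category map, with keep-listed tokens
exempt from category grouping only. Rule sets are validated to be an
idempotent closure — the image of every rule source must be a fixed
point — which guarantees `harmonize ∘ harmonize = harmonize`. Report
files use a comma-separated token field; hyphens are reserved for
compounds, so parsing is unambiguous.

Survey items are ordinal: stress change 1–4 (lowered → high increase)
and five sleep-change items 1–3 coded in the worsening direction
(1 = improved, 3 = worsened; for sleep duration "worsened" means
*shorter* sleep). The worsening-direction coding is what makes all five
stress–sleep Spearman correlations positive.

## Association networks

Co-occurrence is scored at the report level: a word counts once per
report regardless of within-report repetition. For each word pair the
2×2 table over reports yields the phi coefficient, identical to the
Pearson correlation of the binary presence vectors (a property the test
suite checks against `numpy.corrcoef` on random incidence structures).
Pairs with a zero margin (a word present in every report, or in none)
have undefined phi and are excluded.

Retention filters: document frequency ≥ `min_doc_freq` (default 5) and
signed φ strictly > `min_phi` (default 0.2). "Five occurrences" is
interpreted as *reports containing the word* — the incidence notion that
phi itself is computed on — not raw token count; both the floor and the
threshold are configurable. Thresholding is on signed phi by default so
only positive associations form edges; a `keep_negative` flag thresholds
|φ| instead for users who want strong negative association structure.
Words left isolated after edge filtering are dropped: they can belong to
no cluster and have no meaningful centrality. Adjacent-pair (bigram)
counts from the chronological token lists are carried as an edge
attribute but play no role in edge selection. For stratified analyses
the incidence, filters and network are recomputed within the stratum's
reports only; the pooled analysis includes `unspecified` reports.

Edge weights are rounded to 12 decimals at construction so the
fixed-precision TSV artifacts round-trip bit-exactly.

## Spin-glass communities

Communities minimize the weighted Potts Hamiltonian with a
configuration-model null model on node strengths,

    H(σ) = − Σ_{i<j} [ w_ij − γ s_i s_j / (2W) ] δ(σ_i, σ_j),

where w_ij is the edge's phi, s_i the node strength, W the total edge
weight and γ (default 1) the null-model coefficient; at γ = 1 this is
equivalent to maximizing weighted modularity. The null term runs over
*all* same-community pairs, so padding a community with unrelated words
costs energy, and the all-singleton configuration has energy exactly 0.

Optimization is Metropolis annealing over community labels with a
geometric schedule (t: 1 → 0.01, factor 0.99 per sweep, one proposal per
node per sweep), 10 restarts, capped at q = 25 labels per component —
conventional settings for this algorithm family, all exposed as
parameters. The thresholded networks are typically disconnected, so each
connected component is annealed independently (labels can never profit
from spanning components) with globally unique, contiguous cluster ids;
the null model keeps the *global* W so the stored energy is always
reproducible by re-evaluating the Hamiltonian on the stored assignment.
The best state ever visited is kept, the singleton configuration is
always among the candidates (hence returned energy ≤ 0), and the whole
procedure is deterministic given the seed, with ties resolved by the
seeded proposal stream. An exhaustive set-partition enumerator provides
exact ground states for graphs of ≤ 8 nodes; on random small graphs the
annealer is required to reach the enumerated minimum in ≥ 95% of cases
and may never report an energy below it.

## Centrality conventions

Shortest paths are unweighted hop counts by default, matching the
"number of connections from node to another" notion; a weighted mode
with edge length 1/φ exists behind a flag. Betweenness is raw
(unnormalized) Brandes accumulation: endpoints excluded, each unordered
pair counted once, fractional credit across tied shortest paths.
Closeness is the reciprocal of the summed distances to all words in the
node's connected component (0 for a single-node component); the
reciprocal-of-mean variant is available behind a flag. Ranked lists sort
descending with alphabetical tie-break.

A known artifact of component-restricted closeness: nodes in tiny
components (e.g. an isolated word pair) score 1.0 and can top the
closeness ranking of a fragmented network. This is inherent to the
convention, not a bug; compare rankings within the giant component when
that matters.

## Survey statistics

Spearman correlations are tie-aware (Pearson on average ranks, via
scipy, cross-checked against a longhand midrank oracle). Chi-square is
the plain Pearson statistic without continuity correction, df =
(rows−1)(cols−1). Percentage tables round half-up to one decimal, as
printed tables conventionally do, so columns sum to 100 only up to
rounding slack. P-values are reported but nothing downstream consumes
them.

## Synthetic data

**Theme corpora.** Each report draws at most one latent theme with
stratum-specific prevalence; a fraction f of its tokens comes uniformly
from the theme's word set, the rest uniformly from a background
vocabulary, and token order is shuffled. Defaults are six themes of
eight disjoint words each, prevalence 0.15 per theme per stratum (10%
background-only reports), f = 0.8, 400 reports per stratum, 200
background words, report lengths uniform on 4–10. In this well-separated
regime the default pipeline recovers the planted partition with adjusted
Rand index ≈ 1 (the recovery bar in the tests is mean ARI ≥ 0.8 over
five seeds, scored on planted words that survive the filters). Theme
words are disjoint across themes so the planted truth is well defined;
real dream clusters overlap through shared words, which this generator
deliberately does not emulate. Nor does it emulate realistic vocabulary,
Zipfian background frequencies, or respondent-level report correlation —
passing recovery tests therefore demonstrates the pipeline's
correctness on clustered co-occurrence structure, not its performance
on any real corpus.

**Profile-exact corpora.** The corpus-size profile (total tokens/types,
per-stratum tokens/types, a 3-token `unspecified` remainder) is
reproduced exactly by construction: the vocabulary is split into
shared and stratum-exclusive type pools sized from the profile (the
shared pool is pinned by inclusion–exclusion), every type appears at
least once in its stratum, the residual token budget is spread with a
Zipf-like 1/rank multinomial, and tokens are shuffled into reports of
3–9 tokens. Infeasible profiles (more types than tokens, negative
implied sharing) raise with the violated constraint named.

**Copula surveys.** Ordinals are generated by discretizing a latent
one-factor Gaussian at the quantiles of the target marginals: the
stress latent is the common factor, and each sleep item loads on it
with the latent correlation calibrated (monotone bisection, tolerance
0.005) so that the *discretized* pair attains the target Spearman. The
population Spearman of a discretized pair is computed exactly from
bivariate-normal rectangle probabilities and midrank scores. The
one-factor construction makes the joint latent correlation matrix
positive semidefinite for any loadings, so no feasibility repair is
ever needed; it also fixes the item–item correlations to the product of
loadings, which is a modelling choice, not a fitted quantity. Printed
marginal columns that sum to 99.9% (per-cell rounding) are renormalized.
Demographics (age bands, sex) and the stress-dependent probability of
reporting a dream come from the profile's categorical tables.

Default profile values — sample size 4,275; stress marginals
22.1/21.9/38.0/18.0%; the five item marginals; Spearman targets
0.26/0.37/0.43/0.182/0.29; reporting rates 17.8/13.0/20.5/27.4% by
stress level — restate the survey the package emulates.

## Testing and problem sizes

Oracle tests pit every statistical engine against an independent
implementation: phi vs binary-vector Pearson (1,000 random tables,
1e-12), Spearman vs longhand midranks, betweenness vs explicit BFS path
enumeration (30 random graphs ≤ 10 nodes, exact), the annealer vs
exhaustive set-partition enumeration (50 random graphs ≤ 8 nodes), and
the community structure vs igraph's spin-glass implementation on a
barbell graph. Stochastic generator checks use fixed seeds; marginal-
convergence and zero-target checks average over several seeds before
applying their bounds, since a single draw's maximum deviation across
~19 ordinal cells at n = 4,275 sits at the bound for a perfectly
calibrated generator (the generator is verified unbiased at n = 200,000).
Recovery experiments use five seeds of the default theme corpus; the
whole suite runs in well under a minute on one CPU.

## Limitations

- Which nouns are "essential", and cluster labelling, are human steps
  outside this package's scope; cluster labels are annotation inputs.
- The phi threshold is a hard cut; no multiple-testing control or edge
  significance testing is attempted.
- Annealing is a heuristic: ground-state guarantees exist only where the
  exhaustive oracle applies (≤ 8 nodes). Cluster counts on real-size
  networks depend on γ, the spin cap and the schedule.
- The synthetic survey's item–item dependence is single-factor; only the
  stress–item margins are calibrated.
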