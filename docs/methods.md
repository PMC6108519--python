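# Methods

## Model

A recall day contributes one observation per eating occasion: a vector of
gram amounts over 39 food groups. For each main meal the package assumes a
Gaussian copula: amounts are monotone transforms of a latent multivariate
normal vector z ~ N(0, Σ_meal), so dependence between foods is fully
captured by Σ_meal while margins are free. Conditional dependence — which
foods are eaten together *given everything else* — lives in the precision
matrix Ω = Σ⁻¹: food groups i and j share an edge iff ω_ij ≠ 0, with
partial correlation −ω_ij/√(ω_ii ω_jj).

Estimation proceeds in three stages per intake table:

1. **Skeptic correlation.** Spearman mid-rank correlations (Kendall tau-b
   optional) are mapped onto the latent Gaussian scale by
   2 sin(πρ̂/6) resp. sin(πτ̂/2). Rank-based estimation is what makes the
   model robust to the extreme skew and zero inflation of dietary grams.
   The sine-mapped matrix need not be positive semidefinite when columns
   carry massive ties (foods almost never eaten at a meal); eigenvalues are
   clipped at a floor of 1e−4 and the diagonal rescaled to one, repeating
   until the floor holds. Zero-variance columns get zero correlation with
   everything, are flagged, and stay in the node set so all five networks
   share identical nodes.
2. **Graphical lasso.** Ω̂ maximises log det Ω − tr(ŜΩ) − λΣ_{i≠j}|ω_ij|
   (off-diagonal penalty only; the diagonal is unpenalised, so the fitted
   covariance matches Ŝ on the diagonal). The solver is coordinate descent
   with a verified Karush–Kuhn–Tucker residual ≤ 1e−5 as the binding
   convergence contract; on near-singular inputs at small penalties — which
   the 1e−4 eigenvalue floor makes routine — an ADMM solver of the same
   objective takes over, warm-started along the penalty path.
3. **Penalty selection.** Tenfold cross-validation with per-fold re-ranking:
   the skeptic matrix is recomputed on the training rows of each fold, the
   held-out loss is tr(Ŝ_test Ω̂) − log det Ω̂ on the fold's own skeptic
   matrix, and the grid is 30 log-spaced values from λ_max (the largest
   off-diagonal |ŝ|) down to 0.01 λ_max. Mean losses within one standard
   error of the minimum are treated as tied and resolved toward the larger
   (sparser) penalty. This one-standard-error default matters: the
   held-out-likelihood curve is nearly flat below its elbow, and taking the
   exact argmin (`selection_rule="min"`, still available) returns networks
   with several times more edges than the underlying structure — on
   simulated hub graphs the argmin rule selects ~80 edges where 16 are true
   while the path itself contains the exact support. Plain likelihood CV
   is model-selection inconsistent for the lasso; one standard error is the
   conventional correction.

## Tables

- A **meal table** has one row per recall day with positive total intake at
  that occasion (a skipped meal is not an observation); rows are treated as
  independent across participants and days.
- The **habitual table** sums each recall day over all 11 occasions and
  averages the available days per participant, unweighted. Recall days are
  inferred from the records; a hypothetical day with no recorded intake at
  any occasion would not be counted.
- Summary statistics use the sample (n−1) standard deviation.

## Link communities

Communities are clusters of *edges*, so food groups can belong to several
communities. The similarity of two edges sharing node k is the Jaccard
index of the inclusive neighborhoods n⁺(·) of their non-shared endpoints;
non-adjacent edge pairs have similarity 0. Single-linkage agglomeration
over edge pairs gives a dendrogram cut at the level maximising the
partition density

    D = (2/M) Σ_c m_c (m_c − n_c + 1) / ((n_c − 2)(n_c − 1)),

with D_c = 0 for single edges and trees. Ties in D resolve toward the
finer (higher-similarity) cut — deterministic and favouring small,
interpretable communities. Clusters spanning ≥ 3 nodes are reported as
communities; nodes touched by no such cluster are unassigned even when
they carry edges, which reproduces the phenomenon of strongly linked dyads
(e.g. tea–coffee at breakfast) that belong to no community. Centrality is
the number of communities containing a node (central: ≥ 2), ranked
descending with alphabetical tie order. Similarity is computed on the
unweighted edge set; flat clusters at any height equal connected
components of the similarity-thresholded edge graph, which makes the
output invariant to node relabelling. A brute-force maximiser over all
threshold levels (and, for ≤ 6 edges, over all partitions of edges into
connected clusters) serves as the testing oracle; note the unrestricted
partition optimum can exceed the best dendrogram cut (smallest example:
a 5-cycle with a pendant edge, D = 5/36 vs 1/10), so the dendrogram cut is
the defined estimand, as in the clustering algorithm itself.

## Meal-versus-habitual comparison

Edges are matched direction-specifically: unordered food pair plus the sign
of the partial correlation (a sign-agnostic mode exists). Only edges inside
identified networks (components of ≥ 3 groups) are compared, with multiple
components of one meal pooled. Reported per meal: matched/total and the
percentage to one decimal, with an explicit "empty" marker (not 0%) for
edgeless networks; plus the percentage of habitual edges found in no meal
network, sign-discordant pairs, and mean/max |pcor| per network.

## Synthetic cohort

The generator is the package's stand-in for the (non-deposited) cohort
recalls and defines the study conditions end to end:

- **Design:** 814 participants; 3 with one recall day, 5 with two, the rest
  with three (seeded draws from those proportions); 11 eating occasions of
  which breakfast, lunch, afternoon snack and dinner are main meals.
- **Latent structure:** one sparse signed graph per meal, assembled from
  reported meal-level relations (bread with spreads and toppings at
  breakfast; potatoes–red meat–cabbages at lunch; coffee–cakes–dairy at the
  afternoon snack; mutually exclusive beverages at dinner), each edge at
  target |pcor| 0.35. `make_precision` realises a requested support by
  damped iterative rescaling of edge weights under a diagonally dominant
  diagonal (ω_ii = 1 + Σ_j|ω_ij| + 0.01), which guarantees positive
  definiteness at every step; a degree-d node cannot carry equal partial
  correlations above 1/√d, so edges at dense nodes saturate slightly below
  target (tolerated to ±0.05) and genuinely infeasible requests raise. The
  "hub" benchmark topology is disjoint stars of five nodes for the same
  reason.
- **Margins:** per meal and food group, a point mass at zero plus a
  lognormal positive part (gamma optional), moment-matched to published
  per-meal means/SDs: with positive-part coefficient of variation fixed at
  0.8 the zero mass absorbs the remaining overdispersion; when none is
  needed the CV is solved exactly; the zero probability is capped at 0.995
  (grams ≈ 0 columns). Amounts: observed = 0 if Φ(z) < π₀, else the
  positive-part quantile at (Φ(z) − π₀)/(1 − π₀) — thresholding the *same*
  latent Gaussian keeps the copula interpretable and makes zero inflation a
  one-sided attenuation that never flips dependence signs.
- **Within-person correlation:** z = √ρ·u_participant + √(1−ρ)·v_day with
  ρ = σ²/(1+σ²) from `participant_effect_sd` (default 0.7, ρ ≈ 0.33, a
  moderate day-to-day consistency; no published estimate exists, so this is
  an exposed free parameter, not a cohort claim). Marginally each day keeps
  exactly the specified meal copula, and day-averaging attenuates
  dependence — the mechanism behind habitual networks being weaker than
  meal networks.
- **Non-meal occasions** draw independent sparse low-level amounts
  (default: 3% eating probability, lognormal around ~15 g), so habitual
  averaging mixes structured and unstructured intake like real snacking.

What the generator does not emulate: interviewer and coding effects,
weekday/weekend structure, energy adjustment, food-item granularity below
the 39 groups, and any dependence *between* different meals of the same
day. Passing tests therefore demonstrate correct recovery of a known
copula structure under realistic margins and design, not performance on
real interviews.

## Problem sizes and numerical choices

Tests and the acceptance script run the preset at its full size (814
participants; meal tables of ≈ 2,430 rows × 39 groups) and the recovery
benchmark at p = 20, n = 2,000; the hub-recovery summary in the acceptance
script averages 3 seeds. Glasso tolerances: solver duality-gap 1e−8 to
1e−10, KKT contract 1e−5, edge support read from exact zeros (tolerance
1e−8 on partial correlations). The strong-edge threshold is inclusive
(|pcor| = 0.30 is strong). Percentages round to one decimal. All
randomness flows from named integer seeds; equal seeds reproduce
byte-identical artifacts, recorded with SHA-256 checksums in the run
manifest.

## Known limitations

- Tenfold likelihood CV, even with the one-standard-error default, still
  over-includes weak false edges relative to the true support on hard
  zero-inflated problems (measured edge F1 ≈ 0.7 on the hub benchmark);
  consistent selection would need stability- or information-criterion-based
  rules, which are deliberately out of scope.
- The skeptic estimator assumes continuous margins; the zero atom biases
  rank correlations of zero-heavy pairs, which the sine map does not
  correct. Sign and ordering of dependencies are preserved.
- Kendall tau-b estimation is O(p² n log n) per table and noticeably slower
  than Spearman at cohort sizes; Spearman is the default.
- Habitual-table rows are participant means of 1–3 days, so the habitual
  network estimates dependence of noisy means — attenuation is expected
  behaviour, not a bug.
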