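# Methods

## Model

A correlation network treats each variable (metabolite) of a samples ×
variables matrix as a vertex and draws an undirected edge between two
variables when their pairwise correlation is both strong and statistically
significant. The fitted object is therefore determined by four choices: the
correlation type, the missing-data policy, the multiple-testing adjustment,
and the two thresholds of the edge rule `|r| ≥ R and p < P`.

### Correlation type

* **Pearson** assumes (bivariate) normal margins; p-values come from the
  exact beta/t form with df = n − 2.
* **Spearman** (default) is Pearson on average ranks; ties receive average
  ranks, and p-values use the t approximation — adequate at n ≈ 30 and the
  standard choice for skewed, outlier-prone abundance data. Exact
  permutation p-values are deliberately out of scope.
* **Kendall** tau-b with the normal approximation is available for
  completeness but is not used by any default.

The Shapiro–Wilk screen (`normality_screen`) recommends Pearson only when
*every* variable's test has p > alpha; any non-normal — or untestable
(< 3 observations) — variable switches the recommendation to Spearman. This
is intentionally conservative: one heavy-tailed variable contaminates all
of its pairs.

### Missing data

Pairwise-complete deletion: each pair is correlated on the samples where
both variables are observed (`n_pairs` records the counts). Listwise
deletion would discard most rows of a sparse matrix. Pairs with fewer than
`min_pairs` (default 4) complete observations, or with a constant variable
on their complete samples, are **undefined**: NaN in every matrix, excluded
from the adjustment family, never selectable as edges. Note the usual
caveat of pairwise deletion: the r matrix is not guaranteed positive
semi-definite; nothing downstream requires it to be.

### Multiple-testing adjustment

The family is the m = v(v−1)/2 unique off-diagonal pairs of one condition's
matrix — never v², and never pooled across conditions (each condition's
network is corrected independently, mirroring how two-condition studies
report per-condition q-values). "FDR" is read as Benjamini–Hochberg
step-up; Bonferroni is available. Undefined pairs shrink m.

### Edge rule

`|r| ≥ R` (inclusive) and `p < P` (strict), with P applied to the adjusted
p by default. The inclusive/strict split honours thresholds quoted as
"r ≥ |±0.7|" while keeping "p < 0.05" strict; both directions are
configurable (`Thresholds.r_inclusive` / `p_inclusive`) and only matter at
exact ties. Negative correlations enter by magnitude and keep their signed
r as the edge weight; no separate sign attribute exists.

## File conventions

* `r_table.csv`: full symmetric r matrix, unit diagonal, labels on both
  axes.
* `p_table.csv`: one square matrix; strictly-lower triangle = raw p,
  strictly-upper = adjusted p, diagonal 0. Readers must reconstruct both
  symmetric matrices from the triangles.
* Edge tables: three tab-delimited columns (source, target, r), no header,
  one row per unordered pair — loadable by Cytoscape as a table. The
  concatenated "A−B" pair label is derived display text only
  (`EdgeRecord.label`), never a file column.
* Numeric output uses 6 significant digits, exceeding the 2–3 decimals of
  typical published tables; label matching is exact and case-sensitive.
* Missing-value tokens on input: empty cell, `NA`, `NaN` (case-insensitive).

## Topology conventions

All shortest paths are unweighted hop counts; correlation weights are
attributes, not distances.

* Vertex betweenness is normalized by (v−1)(v−2)/2 over the **whole**
  graph, unreachable pairs contributing 0 — the undirected NetworkAnalyzer
  convention, which keeps published hub tables in [0, 1]. Edge betweenness
  is left unnormalized.
* "Transitivity" is the global ratio 3·triangles/connected-triples (the
  clique-forming probability); the mean local clustering coefficient is
  reported separately and never under that name. With no connected triple
  the ratio is undefined and reported as 0 with a `transitivity_defined`
  flag.
* Diameter is the maximum eccentricity of the largest connected component;
  when several components tie for largest, the maximum diameter among them
  is taken. The component count is always reported next to it so a
  disconnected graph is visible.
* Average shortest path pools all connected ordered pairs of the whole
  graph into one mean.
* The power-law check is a least-squares line on log(count) vs log(degree)
  over non-empty histogram bins, requiring ≥ 3 distinct positive degrees;
  it is a rough diagnostic, not a maximum-likelihood tail fit.
* Hub ranking: betweenness descending, ties by degree descending, then
  label ascending — deterministic, so reports are byte-identical across
  runs.

## Network comparison

Edge identity in union/intersection/difference is the unordered label
pair; weights are ignored for membership and come from the first operand
where both carry the edge. Every set operation drops vertices left without
an incident edge. For the difference this is what shrinks the vertex set
relative to the minuend (a vertex whose every edge is shared disappears
from the unique-interaction network); for the union it is a no-op on
networks built from edge tables, which never contain isolated vertices.
Whether a published merge kept degree-0 vertices in a union is generally
unknowable from printed counts; dropping them everywhere is the consistent
choice and is what this package does.

## Synthetic data

The generator emulates a two-condition targeted-metabolomics experiment:
default 30 samples per condition and 24 variables — one 6-variable block
shared by both conditions, one 5-variable block specific to each condition,
and 8 unstructured noise variables. Correlated blocks use a single latent
factor, x_j = √ρ·f + √(1−ρ)·ε_j with f, ε_j standard normal, so every
within-block pair has population correlation exactly ρ (default 0.9) and
unit variance; 5% of entries are masked completely at random. Sample sizes,
block correlation and thresholds match the regime the pipeline is intended
for (n = 30, |r| ≥ 0.7, q < 0.05); the block sizes, counts, noise-variable
count and 5% missing rate are the package's own choice of a realistic small
profiling panel, fixed once.

What the generator does **not** emulate: GC-MS-like skewed intensity
distributions, heteroscedastic or informative missingness, batch effects,
or biochemical pathway structure. A green planted-block recovery test
therefore establishes that the statistical machinery (rank correlation,
BH, thresholding, set operations) recovers a known correlation structure
at the stated n and ρ — not that any particular biological data set would
be reconstructed.

## Numerical and degenerate-input choices

* Density is NaN below 2 vertices; diameter requires ≥ 1 edge; betweenness
  is all-zero below 3 vertices; average shortest path is NaN with no
  connected pair.
* r = ±1 yields p = 0 exactly; BH and Bonferroni cap at 1.
* Duplicate unordered pairs: rejected when statistics conflict
  (`build_network`), collapsed to the first occurrence on file ingestion
  (`read_edge_table`), matching how a visualisation tool tolerates
  redundant rows.
* Self-loop rows in edge files are skipped with a warning rather than
  rejected, since exported adjacency tables sometimes carry diagonal
  entries.
* All simulation randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawning, so conditions are independent but
  jointly reproducible.

## Known limitations

* No partial correlations, shrinkage estimators, permutation-based FDR,
  community/module detection, or weighted-path metrics.
* The t approximation for Spearman p-values is slightly anticonservative
  below n ≈ 10; with the default thresholds this only matters for
  borderline pairs.
* Betweenness normalization is whole-graph; per-component normalization
  would inflate values in small disconnected fragments and is not offered.
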