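# corrnet

Correlation-based network construction, topology analysis and differential
comparison for omics-scale data matrices.

## The problem

Targeted metabolite profiling (and, equally, any moderate-width omics assay)
yields a samples × variables matrix — typically a few dozen samples, 20–500
variables, with missing values. A standard way to summarise the coordinated
behaviour of the variables is a **correlation network**: an undirected graph
whose vertices are variables and whose edges are the statistically
significant pairwise correlations. Comparing the networks fitted under two
experimental conditions (e.g. normoxia vs. hypoxia in tumour cell cultures)
then exposes condition-specific rewiring that single-variable statistics
miss: edges unique to one condition, and hub metabolites that coordinate
them.

`corrnet` implements that whole workflow as a library plus a small CLI:

1. **Correlation stage.** For every unordered pair (i, j) of variables,
   compute r_ij (Pearson, Spearman or Kendall) on the pairwise-complete
   samples, its two-sided p-value, and the p-value adjusted over the
   m = v(v−1)/2 simultaneous tests (Benjamini–Hochberg FDR or Bonferroni).
   A Shapiro–Wilk screen recommends Pearson vs. Spearman. The output is the
   classic spreadsheet pair: a symmetric `r_table.csv` and a single square
   `p_table.csv` whose strictly-lower triangle holds raw p-values and
   strictly-upper triangle the adjusted ones.
2. **Edge selection.** The indicator rule `|r_ij| ≥ R and q_ij < P`
   (defaults R = 0.7, P = 0.05 on BH-adjusted q) selects edges; the result
   is a three-column tab-delimited edge table directly importable by
   Cytoscape. Variables with no significant partner never enter the graph.
3. **Topology.** NetworkAnalyzer-style metrics: density 2e/(v(v−1)),
   diameter and average shortest path (unweighted hops), global transitivity
   3·triangles/triples, per-vertex degree, normalized betweenness
   centrality (2/((v−1)(v−2))), local clustering, per-edge betweenness, an
   optional log-log power-law fit, and hub ranking (betweenness ↓, then
   degree ↓, then label).
4. **Comparison.** Union / intersection / difference of two condition
   networks on unordered label pairs; vertices left isolated by a set
   operation are dropped, so a difference network reports only the
   condition-specific subgraph.

A seeded synthetic-data generator plants latent-factor correlation blocks
(x_j = √ρ·f + √(1−ρ)·ε_j) shared between or specific to two conditions, so
the entire pipeline is testable with known ground truth.

## Worked example

```python
from corrnet import (CorrelationNetworkModel, default_spec,
                     network_difference, simulate_paired_conditions)

spec = default_spec(seed=1)              # 30 samples, 24 metabolites,
cond_a, cond_b = simulate_paired_conditions(spec)  # planted rho=0.9 blocks

res_a = CorrelationNetworkModel(cond_a, method="spearman").fit(r_min=0.7,
                                                               p_max=0.05)
print(res_a.summary())
```

```
        Correlation Network Results
==============================================
Condition:                  a
Samples:                    30
Variables:                  24
Correlation method:         spearman
Adjustment:                 BH over m=276 pairs
Thresholds:                 |r| >= 0.7, adjusted (q) p < 0.05
----------------------------------------------
Vertices:                   11
Edges:                      25
Density:                    0.455
Diameter:                   1 (2 component(s))
Transitivity:               1.000
Avg shortest path:          1.000
...
```

The 11 vertices / 25 edges are exactly the planted structure of condition
"a": one shared 6-variable block (15 pairs) and one condition-specific
5-variable block (10 pairs); the 8 noise variables stay out of the network.
Subtracting the other condition's network isolates the specific block:

```python
res_b = CorrelationNetworkModel(cond_b, method="spearman").fit()
diff = network_difference(res_a.network, res_b.network)
print(diff.number_of_nodes(), diff.number_of_edges())   # -> 5 10
```

The same run from the shell:

```bash
corrnet simulate --seed 1 --out sim_
corrnet pipeline --input-a sim_condition_a.csv --input-b sim_condition_b.csv \
        --r-min 0.7 --q-max 0.05 --out run_
```

which writes, per condition, `r_table.csv` / `p_table.csv`, the edge table,
vertex and global topology CSVs, and the `a_minus_b` / `b_minus_a` / `union`
comparison networks.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline from scratch at the given seed: it simulates the
two-condition data set, fits both correlation networks at |r| ≥ 0.7 and
q_BH < 0.05, builds both difference networks, prints their sizes, planted
edge recall and topology summaries, and writes the JSON results object.

## Layout

```
src/corrnet/
  datamatrix.py   DataMatrix container
  correlation.py  correlate / adjust_pvalues / normality_screen
  network.py      thresholds, edge tables, set operations
  topology.py     metrics and reports
  io.py           CSV / dual-triangle / edge-table / SIF / GraphML
  synthetic.py    planted-block generator
  model.py        CorrelationNetworkModel / CorrelationNetworkResults
  cli.py          corrnet correlate|network|analyze|compare|simulate|pipeline
```

See `docs/methods.md` for the statistical conventions and their rationale.
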