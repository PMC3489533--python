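# protnet

Knowledge-based analysis of proteomics lists on a directed, mechanism-
annotated protein interaction graph.

A proteomics experiment yields a *list* of proteins, not a mechanism.
`protnet` interprets such lists against a global interactome — a directed
multigraph whose edges carry a mechanism (binding, phosphorylation,
transcription regulation, ...), a causative effect and a species tag — with
four families of tools sharing one statistical core:

* **Ontology enrichment** — map the list onto gene-set collections (GMT)
  and rank terms by the upper-tail hypergeometric p-value against a
  configurable background universe, with Benjamini–Hochberg FDR control.
* **Interactome over-connectivity** — for every candidate protein, compare
  its number of one-step neighbors inside the list with the hypergeometric
  expectation, reporting expected count, connectivity ratio, p-value and
  z-score per protein class (transcription factors, receptors, ligands,
  kinases, phosphatases, proteases, enzymes).
* **Hidden nodes** — score every intermediary on shortest directed paths
  among the list members: a node i is significant for seed j when it sits
  inside the shortest-path networks of more seed pairs (K_ij of K−1) than
  its global path traffic (N_ij of N−2) predicts; the topological score is
  the minimum p_ij over seeds.  Highly ranked nodes are typically *absent*
  from the measured list — regulators invisible to the assay.
* **Network generation** — seven builder algorithms (direct interactions,
  expand-by-one, shortest paths, auto-expand, analyze-network and its
  TF/receptor variants, transcription regulation, canonical pathway models)
  that decompose the neighborhood of a root list into ranked, size-bounded
  fragments scored by seed enrichment (p, z) and canonical pathway content
  (g-score = z + 1.25 per pathway).

## The statistical core

All four families reduce to sampling without replacement.  With a universe
of `N` objects, `R` marked, and a drawn subset of `n`, the intersection `r`
follows the hypergeometric law

    p(r, n, R, N) = C(R, r) C(N−R, n−r) / C(N, n)

with `μ = nR/N`, `σ² = nq(1−q)(1−(n−1)/(N−1))`, `q = R/N`, and the
enrichment p-value is the upper tail `P(X ≥ r)`.  The z-score `(r−μ)/σ` is
reported alongside but never substituted for the exact tail.  What changes
between tools is only the *instantiation* of (r, n, R, N): term overlap for
enrichment, neighbor counts for connectivity, path-membership counts for
hidden nodes, seed content for network fragments.

## Worked example

Generate a synthetic 500-protein interactome, plant a regulator wired to 10
of 30 seed proteins, and scan for over-connectivity:

```python
from protnet.simulate import FixtureSpec, generate_graph, plant_overconnected_hub
from protnet.interactome import scan_overconnected, report_table

g = generate_graph(FixtureSpec(n_nodes=500, attachment_parameter=3, seed=1))
g, seeds, hub = plant_overconnected_hub(g, n_seeds=30, hub_links=10, seed=1)
report = scan_overconnected(g, seeds)
print(report_table(report).sort_values("p_value").head(3).to_string(index=False))
```

prints

```
               class object  actual  n  R   N  expected     ratio      p_value   z_score      q_value
transcription_factor   P003      10 30 11 499  0.661323 15.121212 1.320939e-12 11.965953 5.151663e-11
               other   P045       3 30  8 499  0.480962  6.237500 8.972281e-03  3.773264 5.156946e-01
               other   P181       3 30  8 499  0.480962  6.237500 8.972281e-03  3.773264 5.156946e-01
```

The planted node `P003` has degree R = 11, of which 10 neighbors fall in the
30-protein seed list against an expectation of 0.66 — a connectivity ratio
of 15.1 and z ≈ 12.0 — and it is the only protein surviving FDR control
(q ≈ 5e-11); the runners-up are chance neighbors of 2–3 seeds with q > 0.5.

The same analyses are available from the shell:

```
protnet simulate --n-nodes 500 --seed 1 --plant hub --out sim/
protnet connect --graph sim/edges.tsv --list sim/seeds.txt --out run/
protnet hidden  --graph sim/edges.tsv --list sim/seeds.txt --out run/
protnet network --graph sim/edges.tsv --list sim/seeds.txt --algorithm an --out run/
```

## Reference values

`scripts/acceptance.py` recomputes, from the package's own code paths, the
reference statistics of the published worked examples: the over-connectivity
p-values and z-scores re-derived from their integer report columns
(r, n, R, N), and the g-score calibration of the network ranking table.

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the models, conventions, numerical choices and
limitations.
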