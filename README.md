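# semwalk

Scale-free semantic networks and memory-foraging random walks.

`semwalk` is a toolkit for a question in computational cognitive science: do
the heavy-tailed inter-response intervals (IRIs) seen in category recall
("name all the animals you can") arise from the *structure* of semantic
memory rather than from an intrinsically heavy-tailed search process? The
package builds semantic networks from document collections, runs a
deliberately simple search process over them — a random walk with retrieval
memory — and tests whether network structure alone reproduces the behavioral
signatures: power-law-like IRI distributions, similarity gradients across
recall positions, and IRIs that grow with network distance.

## The model

**Network construction.** Each concept (e.g., one encyclopedia article per
animal) is reduced to a probability distribution over lemmas; pairwise
dissimilarity is the Jensen–Shannon divergence

    JSD(P‖Q) = ½ D(P‖M) + ½ D(Q‖M),   M = ½(P + Q)

with D the Kullback–Leibler divergence, computed in base 2 so JSD ∈ [0, 1].
An iterative threshold search finds the strictest JSD cutoff at which a
single connected component covers 90% of the documents; pairs at least that
similar become edges. Such networks are scale-free — node degree d follows
an inverse power law P(d) ~ 1/d^β, with β estimated as the negative slope of
a regression on logarithmically binned degrees.

**Search.** A walker starts at a random node and hops to a uniformly random
neighbor each step. Arriving at a node not yet retrieved, it retrieves it
with probability 0.10 and marks it; marked nodes are never retrieved again
(retrieval memory). A run ends after 400 retrievals. Two IRI measures are
recorded per retrieval: the hop count since the previous retrieval, and the
cumulative degree (summed neighborhood sizes) over that span.

**Inference.** Per run, IRI distributions are compared across three
candidate families — Pareto inverse power law P(x) ~ 1/x^α, lognormal, and
exponential — by maximum likelihood and AIC with Akaike weights, each family
defined on the observed support [xmin, ∞). Structure–dynamics analyses add
the lag-based similarity gradient (mean z-scored JSD between items produced
1–10 responses apart) and a one-way ANOVA of log IRIs grouped by the minimal
path length between consecutive retrievals.

Everything is reproducible: a size-matched scrambled control (same nodes and
edge count, edges uniformly random) destroys the structure while preserving
density, and synthetic generators supply topic-clustered corpora,
configuration-model scale-free graphs, and a clustered concept-space network
(ring of power-law-sized subcategory cliques with sparse bridges) so the
full pipeline runs without any external data.

## Worked example

The whole protocol — structured network, scrambled twin, 20 walks × 400
retrievals each, family fits under both IRI measures, path-length ANOVAs —
runs from one command:

```sh
semwalk simulate-all --seed 7 --out demo
```

which prints (about 40 s on one core):

```
semwalk simulation report
config hash: d904422ad7ac246b  master seed: 7

[structured] 5131 nodes, 176467 edges, mean degree 68.78 (synthetic)
  best-fit families (hop measure): lognormal: 20
  best-fit families (degree measure): lognormal: 20
  path-length ANOVA (hop): F(3, 75) = 8.57, p = 5.786e-05
  path-length ANOVA (degree): F(3, 75) = 18.83, p = 3.355e-09

[scrambled] 5131 nodes, 176467 edges, mean degree 68.78 (scrambled)
  best-fit families (hop measure): exponential: 20
  best-fit families (degree measure): exponential: 20
  path-length ANOVA (hop): F(2, 57) = 2257.46, p = 5.366e-55
  path-length ANOVA (degree): F(2, 57) = 2248.29, p = 6.017e-55
```

Reading the report: on the clustered scale-free network every one of the 20
runs produces IRIs best fit by a lognormal (a truncated-power-law-like
heavy tail), and IRIs grow with the network distance between successive
retrievals. On the size-matched random control the same walker produces
memoryless, exponential IRIs in every run — the heavy tail comes from the
search space, not the search rule. (On the control the path-length ANOVA is
still significant because hop counts are mechanically bounded below by path
length; see `docs/methods.md` for why this differs from a structural
effect, and note the control's distances never exceed 3 hops.)

Library use mirrors the CLI. For instance, from a corpus:

```python
from semwalk import (read_corpus_dir, normalize_corpus, pairwise_similarity,
                     find_threshold, build_network, WalkConfig, run_batch,
                     model_select)

docs = read_corpus_dir("articles/")          # one .txt per concept
dists = normalize_corpus(docs)               # lemma probability distributions
matrix = pairwise_similarity(dists)          # all-pairs JSD
thr = find_threshold(matrix, coverage=0.9)   # strictest 90%-coverage cutoff
net = build_network(matrix, thr.threshold, thr.retained_nodes)
traces = run_batch(net, WalkConfig(seed=1), n_runs=20)
print(model_select(traces[0].iris("hop"))[0].family)
```

Subcommands: `sim-matrix`, `build-net`, `scramble-net`, `gen-synthetic`,
`walk`, `fit-iri`, `degree-dist`, `gradient`, `pathlen`, `simulate-all`
(`semwalk <cmd> --help` for flags).

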