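# Methods

This note documents the models and conventions implemented in `semwalk`,
the design choices made where alternatives existed, and what the synthetic
generators do and do not capture about real data.

## Divergences and corpus normalization

Documents are tokenized with a lowercase alphabetic tokenizer and reduced to
relative lemma frequencies after stopword removal. The shipped lemmatizer is
a conservative rule-based inflection stripper (plural -s/-es/-ies, -ing,
-ed with doubled-consonant handling); any `str -> str` normalizer can be
substituted. The stopword list is a plain-text file of ~170 English function
words, overridable per call. Documents with fewer than `min_words` tokens
(default 500, counted before stopword removal, i.e., as running text) are
dropped and reported.

The Kullback–Leibler divergence takes an explicit logarithm base (natural by
default). The Jensen–Shannon divergence is fixed to base-2 logarithms: only
then is JSD exactly bounded by 1, with JSD = 1 iff the supports are
disjoint. JSD needs no smoothing — the mixture M = (P+Q)/2 covers both
supports — while KL returns +infinity when Q lacks mass on P's support
(the divergence's value, not an error). Pairwise JSD is computed over the
union of the two documents' supports.

## Threshold search and controls

"Connect everything at least this similar" is monotone: relaxing the
threshold never shrinks the largest connected component. The coverage search
therefore bisects over the sorted unique off-diagonal values (component
structure only changes at observed values) for the strictest threshold whose
largest component holds at least ceil(coverage x n) nodes, with coverage
defaulting to 0.90. Ties at the threshold are included as edges. "Single
network for 90%" is read as a largest-connected-component criterion; the
nodes outside it are discarded and listed.

The scrambled control redraws the same number of edges uniformly at random
over the same nodes (G(N, M)); its degree distribution is binomial — mean
exactly 2E/N, SD sqrt((N-1)p(1-p)) with p = 2E/(N(N-1)) — so at 5131 nodes
and 175,198 edges the expected degree SD is 8.21. Degree-preserving rewiring
is deliberately *not* used: the control is meant to destroy both the degree
structure and the clustering.

## IRI conventions in the walker

Retrieval happens upon arrival by a hop, so the start node is not eligible
before the first hop and every hop IRI is >= 1. The hop landing on the
retrieved node counts inside its IRI span; the degree measure sums the
degree of every node arrived at during the span, retrieved node included and
revisits counted per arrival. These endpoint conventions are choices, not
forced: the alternative "intervening" reading (landing hop excluded) yields
zero-length IRIs for immediate retrievals, which no log-scale or
positive-support analysis can accommodate. Walks are confined to the largest
component, eligibility (component size >= requested retrievals) is checked
up front, and exceeding the step budget (default 10,000 x retrievals)
returns a flagged partial trace rather than failing. Batch runs derive
per-run seeds from a splittable seed sequence, so run k is identical
whether run alone or in any batch size.

## Heavy-tail fits and model selection

Three continuous families are fit by maximum likelihood and ranked by AIC
(2k − 2 logL; AICc available by flag, negligible at 400 observations per
run), with Akaike weights exp(−Δi/2)/Σ exp(−Δj/2). All three densities are
defined on the observed support [xmin, ∞) with xmin the minimum observation
by default — the convention of the multi-model-inference literature on
movement and interval data, where the measurement floor is part of each
candidate model:

* exponential: location-shifted, rate = 1/mean(x − xmin);
* lognormal: parent lognormal left-truncated at xmin, maximized numerically
  (Nelder–Mead from the closed-form untruncated estimate, which it can only
  improve; when xmin sits deep in the left tail the correction vanishes);
* Pareto: density (α−1) xmin^(α−1)/x^α — α is the exponent as printed for
  P(IRI) ~ 1/IRI^α — with the closed-form MLE α = 1 + n/Σ log(x/xmin).

Anchoring matters: hop IRIs are integers starting at 1, and an exponential
anchored at zero is penalized for the empty interval [0, 1) that the data
can never populate, which would hand geometric (memoryless) data to the
lognormal. `xmin_policy="none"` restores unanchored fits for data genuinely
supported from zero. Ties in AIC (< 1e-9) rank the fewer-parameter family
first. Continuous likelihoods are used although hop IRIs are integers; this
treats IRIs as times, and is a known approximation at small values.

Log-binned analyses use geometric bin edges (5 bins per decade by default),
density = count/(n · width) so densities integrate to 1, and OLS of
log10 density on log10 geometric bin center over occupied bins; for a power
law the negative slope estimates the exponent.

## Synthetic generators

The generators define the package's test conditions; their defaults were
fixed once, from the study protocol's stated sizes (5131 nodes, mean degree
68.3, degree slope 1.14, 20 runs x 400 retrievals at p = 0.10).

**Topic corpus.** Single-membership topics: each topic draws a base lemma
distribution from a symmetric Dirichlet (concentration 1 by default, 200
lemmas), each document multinomially samples 1000 tokens from its topic.
This yields the one property the pipeline presumes — within-topic JSD below
between-topic JSD — and nothing else about real text: no Zipfian
frequencies, no syntax, no mixed-topic documents.

**Configuration-model scale-free graph.** Degrees drawn from
P(d) ~ d^(−1.14) truncated to [1, d_max], with d_max solved by bisection as
the smallest cutoff whose truncated mean reaches the target (723 at the
defaults); stubs paired by iterated random matching with rejection of
self-loops and duplicates (re-queueing rejected stubs, dropping the small
unresolvable residue); largest component returned. Realized mean degree
lands within a few percent of target and the log-binned slope within ~0.15
of −1.14.

**Clustered concept-space network.** A configuration-model graph, however,
is locally tree-like: a walker on it mixes globally in a few hops, its IRIs
stay near-geometric, and the heavy-tailed IRI phenomenon never appears. A
similarity-*threshold* graph is structurally different in kind: it is a
metric neighborhood graph, so hubs are centers of dense regions rather than
global connectors, neighborhoods overlap (high clustering), and a walker
genuinely diffuses through concept space — which is what lets retrieval
memory deplete a region and stretch the IRI tail. The stand-in for such
networks models the category's subcategory structure directly: subcategory
cliques whose sizes follow P(s) ~ s^(−2.14) (a clique member's degree is its
clique size minus one, so node degrees follow P(d) ~ d^(−1.14) by
construction), arranged on a ring with one bridge edge between adjacent
cliques and one long-range shortcut per clique at a ring distance drawn from
P(Δ) ~ 1/Δ (related categories at all scales, navigable-small-world style).
Clique-size counts are allocated deterministically from the size law
(sampling them would let the single largest draw swing the realized mean
degree); the size cutoff is solved against the realized integer allocation
to hit the target mean degree, and the minimum clique size is 3, the
smallest value whose allocation can reach mean degree 68.3 at 5131 nodes.
At the defaults this yields ~560 cliques, largest ~380, mean degree 68.8,
log-binned degree slope −1.14 (r² = 0.99), and consecutive-retrieval path
lengths of 1–4 for ~96% of pairs. Bridges are per clique, not per node:
cross-category similarity is a property of category adjacency (a few
boundary concepts), which is also what makes large depleted cliques slow to
escape — the mechanism behind the lognormal-like IRI tails.

What these stand-ins do not capture: real subcategories are neither
disjoint nor internally complete; real degree distributions are not exact
truncated power laws; and real cross-category structure is hierarchical
rather than ring-plus-shortcuts. Passing tests on them show that the
pipeline's inferences respond correctly to the presence and absence of
clustered scale-free structure — not that any particular corpus has it.

## Structure–dynamics analyses

The similarity gradient z-normalizes each sequence's pairwise JSDs by the
mean and population SD (ddof = 0) of all unordered pairs among that
sequence's distinct items, then averages over ordered position pairs at each
lag 1–10; batch results combine runs weighted by pair counts. The stored
quantity is the z of JSD (higher = less similar); a plotting layer may
negate it for a similarity axis.

Minimal path lengths are breadth-first distances (scipy's unweighted
shortest paths over a CSR adjacency, unique sources chunked); unreachable
pairs are reported as missing, never infinite. The path-length analysis
groups log10 IRIs of consecutive retrieval pairs by their minimal path
length, lengths 1–4 (beyond 4 the data thin out to a few percent), and runs
a classical one-way ANOVA. By default each run contributes one mean per
length group — the ANOVA unit is the run, giving dfs like F(3, 76) at 20
runs and four groups; pooling individual pairs is available by flag. Empty
groups are dropped with a warning and the dfs adjust.

One caveat is intrinsic to hop-counted IRIs: an IRI can never be smaller
than the path length it spans (an IRI of 1 forces adjacency), so even a
structureless control shows a significant ANOVA at these sample sizes. The
structural effect proper shows up in the *range* of distances (the control's
consecutive retrievals never exceed 3 hops, the clustered network reaches
5+ with a heavy tail) and in the growth of group means with length on the
structured network, both of which the test suite asserts.

## Numerical and degenerate-input conventions

Probabilities must sum to 1 within 1e-9 (distributions renormalize after
text round-trips); similarity matrices must be symmetric within 1e-12 and
are re-symmetrized after TSV round-trips. Fits require >= 2 positive values
and fail explicitly on degenerate data (all values equal). ANOVA with
identical data in every group returns F = 0, p = 1; zero within-group
variance with distinct means returns F = infinity, p = 0. Gradient
computation fails explicitly when all pairwise values are equal (zero SD).
The pipeline report contains no timing or environment data, so a fixed
config file and master seed reproduce it bit-for-bit.

## Known limitations

* Exact replication of any particular corpus network (thresholds, slopes)
  requires that corpus; the package reproduces the *protocol* and its
  qualitative contrasts on synthetic conditions sized to the study.
* Continuous likelihoods on integer hop counts bias fits at the smallest
  values; the xmin anchoring absorbs most, not all, of this.
* The scrambled-control path-length ANOVA is significant here for the
  mechanical reason above; treat the ANOVA as meaningful on structured
  networks and rely on the distance-range contrast for controls.
* The walker has no spreading activation, no parallel walkers, and no
  patch-switching policy; it is deliberately the simplest memory-bearing
  dynamic.
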