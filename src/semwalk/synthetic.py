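"""Synthetic fixtures with the statistical structure the pipeline assumes.

Three generators:

* a topic-clustered corpus (documents sampled from per-topic lemma
  distributions), whose within-topic JSD is lower than between-topic JSD —
  the clustered structure an encyclopedic corpus of category members shows;
* a scale-free network with degrees drawn from a truncated power law
  P(d) ~ d**(-exponent) assembled by configuration-model stub pairing — a
  stand-in for the thresholded-similarity semantic network (log-binned
  degree slope near 1.14, mean degree near 68.3 at the default spec);
* a clustered concept-space network — a ring of subcategory cliques with
  power-law sizes, sparse bridges, and distance-decaying shortcuts — the
  stand-in for a similarity-thresholded semantic network, whose modular,
  metric structure is what traps a memory-bearing walker and stretches its
  inter-response intervals (degree slope near 1.14 and mean degree near
  68.3 at the default spec);
* a uniform random simple graph with exact node/edge counts — the
  size-matched control.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .corpus import Document
from .netbuild import NetworkError, SemanticNetwork


class SyntheticError(ValueError):
    """Raised for infeasible generator specifications."""


@dataclass(frozen=True)
class TopicCorpusSpec:
    """Specification for a topic-clustered synthetic corpus.

    Each topic draws a base lemma distribution from a symmetric Dirichlet
    with parameter ``within_topic_concentration``; each document samples
    ``tokens_per_doc`` tokens i.i.d. from its topic's base distribution.
    Large concentration -> topics converge on the uniform distribution and
    all documents look alike; small concentration -> sharply distinct topics.
    """

    n_topics: int = 4
    docs_per_topic: int = 25
    vocab_size: int = 200
    tokens_per_doc: int = 1000
    within_topic_concentration: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_topics", "docs_per_topic", "vocab_size", "tokens_per_doc"):
            if getattr(self, name) < 1:
                raise SyntheticError(f"{name} must be >= 1")
        if self.within_topic_concentration <= 0:
            raise SyntheticError("within_topic_concentration must be > 0")


@dataclass(frozen=True)
class ScaleFreeSpec:
    """Specification for the truncated-power-law configuration model.

    ``d_max`` may be given explicitly; when ``None`` it is solved numerically
    as the smallest cutoff whose truncated power-law mean reaches
    ``target_mean_degree`` (the cutoff is the free knob — with an exponent
    near 1 the distribution mean is controlled almost entirely by the upper
    truncation).
    """

    n_nodes: int = 5131
    degree_exponent: float = 1.14
    d_min: int = 1
    d_max: int | None = None
    target_mean_degree: float = 68.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.degree_exponent <= 0:
            raise SyntheticError("degree_exponent must be > 0")
        if not (1 <= self.d_min):
            raise SyntheticError("d_min must be >= 1")
        if self.d_max is not None and not (
            self.d_min <= self.d_max < self.n_nodes
        ):
            raise SyntheticError("need d_min <= d_max < n_nodes")


def _lemma_name(i: int) -> str:
    """Alphabetic pseudo-lemma (``waaa``, ``waab``, ...): must survive the
    corpus tokenizer, which keeps only alphabetic tokens."""
    letters = []
    for _ in range(3):
        i, r = divmod(i, 26)
        letters.append(chr(ord("a") + r))
    return "w" + "".join(reversed(letters))


def generate_topic_corpus(spec: TopicCorpusSpec) -> list[Document]:
    """Sample a topic-clustered corpus; doc_id is ``t{topic}_d{doc}``.

    Documents are single-membership (one topic each); lemma names are
    alphabetic pseudo-words. Byte-identical output for identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    vocab = [_lemma_name(i) for i in range(spec.vocab_size)]
    docs: list[Document] = []
    alpha = np.full(spec.vocab_size, spec.within_topic_concentration)
    for t in range(spec.n_topics):
        base = rng.dirichlet(alpha)
        for d in range(spec.docs_per_topic):
            counts = rng.multinomial(spec.tokens_per_doc, base)
            tokens: list[str] = []
            for w, c in zip(vocab, counts):
                tokens.extend([w] * int(c))
            # shuffle so token order carries no signal
            perm = rng.permutation(len(tokens))
            text = " ".join(tokens[i] for i in perm)
            docs.append(Document(f"t{t}_d{d}", text))
    return docs


def truncated_powerlaw_pmf(exponent: float, d_min: int, d_max: int) -> np.ndarray:
    """P(d) ~ d**(-exponent) on integers [d_min, d_max], normalized."""
    d = np.arange(d_min, d_max + 1, dtype=float)
    w = d**(-exponent)
    return w / w.sum()


def solve_dmax_for_mean(
    exponent: float, d_min: int, target_mean: float, n_nodes: int
) -> int:
    """Smallest integer cutoff whose truncated power-law mean >= target.

    The mean is strictly increasing in the cutoff, so bisection applies.
    """
    def mean_at(d_max: int) -> float:
        d = np.arange(d_min, d_max + 1, dtype=float)
        w = d**(-exponent)
        return float((d * w).sum() / w.sum())

    hi = n_nodes - 1
    if mean_at(hi) < target_mean:
        raise SyntheticError(
            f"target mean degree {target_mean} unreachable with exponent "
            f"{exponent} and n_nodes {n_nodes}"
        )
    lo = d_min
    while lo < hi:
        mid = (lo + hi) // 2
        if mean_at(mid) >= target_mean:
            hi = mid
        else:
            lo = mid + 1
    return hi


def generate_scalefree_network(spec: ScaleFreeSpec) -> SemanticNetwork:
    """Configuration-model graph with truncated-power-law degrees.

    Degrees are sampled from P(d) ~ d**(-exponent) on [d_min, d_max] (the
    last degree is resampled until the stub total is even). Stubs are paired
    by iterated random matching: shuffle, pair, keep pairs that are neither
    self-loops nor duplicates, re-queue the stubs of rejected pairs, and
    repeat up to a retry budget; the (small) unresolvable residue is dropped.
    Returns the largest connected component, node ids ``n0 ... n{k}``.
    """
    rng = np.random.default_rng(spec.seed)
    d_max = spec.d_max
    if d_max is None:
        d_max = solve_dmax_for_mean(
            spec.degree_exponent, spec.d_min, spec.target_mean_degree, spec.n_nodes
        )
    if not (spec.d_min <= d_max < spec.n_nodes):
        raise SyntheticError("need d_min <= d_max < n_nodes")
    pmf = truncated_powerlaw_pmf(spec.degree_exponent, spec.d_min, d_max)
    support = np.arange(spec.d_min, d_max + 1)
    degrees = rng.choice(support, size=spec.n_nodes, p=pmf)
    while degrees.sum() % 2 == 1:
        degrees[-1] = rng.choice(support, p=pmf)

    edges: set[tuple[int, int]] = set()
    stubs = np.repeat(np.arange(spec.n_nodes), degrees)
    retry_budget = 200
    for attempt in range(retry_budget):
        if len(stubs) < 2:
            break
        rng.shuffle(stubs)
        if len(stubs) % 2 == 1:  # can only happen after residue trimming
            stubs = stubs[:-1]
        a, b = stubs[0::2], stubs[1::2]
        lo, hi_ = np.minimum(a, b), np.maximum(a, b)
        leftover: list[int] = []
        made_progress = False
        for u, v in zip(lo.tolist(), hi_.tolist()):
            if u == v or (u, v) in edges:
                leftover.extend((u, v))
            else:
                edges.add((u, v))
                made_progress = True
        stubs = np.asarray(leftover, dtype=np.int64)
        if not made_progress:
            break
    else:
        if len(stubs) > 0.05 * 2 * len(edges):
            raise SyntheticError(
                "stub pairing failed to converge; try a smaller d_max, a larger "
                "n_nodes, or a steeper exponent"
            )
    # residue (stubs that can no longer be placed without duplicates) is dropped

    g = nx.Graph()
    g.add_nodes_from(range(spec.n_nodes))
    g.add_edges_from(edges)
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(sorted(comp)).copy()
    g = nx.relabel_nodes(g, {v: f"n{v}" for v in g.nodes})
    return SemanticNetwork(g, provenance="synthetic")


@dataclass(frozen=True)
class SemanticSpaceSpec:
    """Specification for the clustered concept-space network.

    The model: semantic memory for a category is a set of subcategories
    (farm animals, sea creatures, ...) whose sizes are heavy-tailed. Each
    subcategory is a clique (every member above the similarity threshold
    with every other); adjacent subcategories on a ring share one bridge
    edge (boundary concepts), and each subcategory has one long-range
    shortcut whose ring distance decays as a power law (related categories
    at all scales). Since a member's degree is its subcategory size minus
    one, drawing sizes s with P(s) ~ s**-(degree_exponent + 1) makes the
    node-level degree distribution follow P(d) ~ d**-degree_exponent by
    construction; the size cutoff is solved numerically so the realized
    mean degree meets ``target_mean_degree``.
    """

    n_nodes: int = 5131
    degree_exponent: float = 1.14
    target_mean_degree: float = 68.3
    min_cluster_size: int = 3
    bridges_per_clique: int = 1
    shortcut_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.degree_exponent <= 0:
            raise SyntheticError("degree_exponent must be > 0")
        if self.min_cluster_size < 2:
            raise SyntheticError("min_cluster_size must be >= 2")
        if self.n_nodes < 2 * self.min_cluster_size:
            raise SyntheticError("n_nodes too small for two clusters")
        if self.bridges_per_clique < 0:
            raise SyntheticError("bridges_per_clique must be >= 0")


def _clique_size_allocation(
    n: int, size_exp: float, smin: int, smax: int
) -> list[int]:
    """Deterministic integer clique sizes following P(s) ~ s**-size_exp.

    Node mass at size s is proportional to s**(1 - size_exp); counts are
    materialized largest-first with remainder carry, and the node total is
    padded/trimmed with minimum-size cliques so it equals ``n`` exactly.
    Deterministic allocation keeps the heavy tail stable across seeds
    (sampling the sizes would make the realized mean degree swing with the
    single largest draw).
    """
    s = np.arange(smin, smax + 1, dtype=float)
    node_share = s ** (1.0 - size_exp)
    node_share /= node_share.sum()
    counts: list[int] = []
    rem = 0.0
    for si, share in zip(s[::-1], node_share[::-1]):
        t = n * share / si + rem
        k = int(t)
        rem = t - k
        counts.extend([int(si)] * k)
    total = sum(counts)
    while total + smin <= n:
        counts.append(smin)
        total += smin
    if total < n and counts:
        counts[-1] += n - total
    return counts


def _allocation_mean_degree(n: int, size_exp: float, smin: int, smax: int) -> float:
    sizes = _clique_size_allocation(n, size_exp, smin, smax)
    return sum(s * (s - 1) for s in sizes) / sum(sizes)


def solve_size_cutoff_for_mean(
    n: int, size_exp: float, smin: int, target_mean: float
) -> int:
    """Smallest clique-size cutoff whose allocation reaches the mean degree."""
    lo, hi = smin, n
    if _allocation_mean_degree(n, size_exp, smin, hi) < target_mean:
        raise SyntheticError(
            f"target mean degree {target_mean} unreachable with size exponent "
            f"{size_exp}, min cluster {smin}, n_nodes {n}"
        )
    while lo < hi:
        mid = (lo + hi) // 2
        if _allocation_mean_degree(n, size_exp, smin, mid) >= target_mean:
            hi = mid
        else:
            lo = mid + 1
    return hi


def generate_semantic_space_network(spec: SemanticSpaceSpec) -> SemanticNetwork:
    """Clustered concept-space network; see :class:`SemanticSpaceSpec`.

    Always connected (the bridge ring spans every clique); node ids
    ``n0 ... n{k}``; provenance = synthetic. Deterministic under seed: the
    clique-size allocation is fixed by ``spec``, the seed randomizes the
    ring arrangement, membership, and bridge/shortcut endpoints.
    """
    rng = np.random.default_rng(spec.seed)
    size_exp = spec.degree_exponent + 1.0
    smax = solve_size_cutoff_for_mean(
        spec.n_nodes, size_exp, spec.min_cluster_size, spec.target_mean_degree
    )
    sizes = _clique_size_allocation(
        spec.n_nodes, size_exp, spec.min_cluster_size, smax
    )
    rng.shuffle(sizes)
    n_clusters = len(sizes)
    perm = rng.permutation(spec.n_nodes)
    g = nx.Graph()
    g.add_nodes_from(range(spec.n_nodes))
    members: list[list[int]] = []
    start = 0
    for s in sizes:
        mem = [int(v) for v in perm[start : start + s]]
        start += s
        members.append(mem)
        g.add_edges_from(
            (mem[i], mem[j]) for i in range(s) for j in range(i + 1, s)
        )
    # bridge ring: one edge between each pair of ring-adjacent cliques
    for c in range(n_clusters):
        u = int(rng.choice(members[c]))
        v = int(rng.choice(members[(c + 1) % n_clusters]))
        g.add_edge(u, v)
    # long-range shortcuts with power-law ring distance
    dist = np.arange(1, max(n_clusters // 2, 2))
    pd = dist ** (-float(spec.shortcut_exponent))
    pd /= pd.sum()
    for c in range(n_clusters):
        for _ in range(spec.bridges_per_clique):
            d = int(rng.choice(dist, p=pd)) * (1 if rng.random() < 0.5 else -1)
            u = int(rng.choice(members[c]))
            v = int(rng.choice(members[(c + d) % n_clusters]))
            if u != v:
                g.add_edge(u, v)
    g = nx.relabel_nodes(g, {v: f"n{v}" for v in g.nodes})
    return SemanticNetwork(g, provenance="synthetic")


def generate_random_network(
    n_nodes: int, n_edges: int, seed: int
) -> SemanticNetwork:
    """Uniform random simple graph with exactly the requested counts.

    Edges are drawn uniformly without replacement from all unordered
    non-self pairs; mean degree is exactly 2E/N. Same contract as
    :func:`semwalk.netbuild.scramble_network` but without a template.
    """
    if n_nodes < 1:
        raise SyntheticError("n_nodes must be >= 1")
    if not (0 <= n_edges <= n_nodes * (n_nodes - 1) // 2):
        raise NetworkError(
            f"{n_edges} edges infeasible on {n_nodes} nodes "
            f"(max {n_nodes * (n_nodes - 1) // 2})"
        )
    g = nx.gnm_random_graph(n_nodes, n_edges, seed=random.Random(int(seed)))
    g = nx.relabel_nodes(g, {v: f"n{v}" for v in g.nodes})
    return SemanticNetwork(g, provenance="synthetic")
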