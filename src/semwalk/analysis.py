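"""Structure-dynamics analyses linking network structure to recall order.

Three analyses connect where a retrieval sequence went in the network to how
similar and how far apart the retrieved concepts are:

* the similarity gradient — mean z-normalized pairwise divergence between
  items produced 1..L responses apart (clustered retrieval shows low
  divergence at short lags rising with lag; a scrambled control is flat);
* minimal path lengths — fewest hops between consecutive retrievals;
* the path-length effect — one-way ANOVA of log-transformed IRIs grouped by
  the minimal path length between consecutive retrievals (structured
  networks show IRIs growing with distance; controls do not).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .corpus import SimilarityMatrix
from .netbuild import SemanticNetwork
from .walker import WalkTrace

logger = logging.getLogger(__name__)


class AnalysisError(ValueError):
    """Raised for invalid analysis inputs."""


@dataclass
class GradientResult:
    """Mean z-normalized divergence by positional lag."""

    lags: list[int]
    mean_z: list[float]
    n_pairs: list[int]


@dataclass
class PathLengthResult:
    """Grouped log-IRIs by minimal path length, with the one-way ANOVA."""

    lengths: list[int]
    log_iris_by_length: list[np.ndarray]
    f_stat: float
    df_between: int
    df_within: int
    p_value: float


def similarity_gradient(
    sequence: Sequence[str], matrix: SimilarityMatrix, max_lag: int = 10
) -> GradientResult:
    """Mean z-scored pairwise value at each positional lag 1..max_lag.

    The z-normalization population is all unordered pairs among the distinct
    items of this sequence (mean and population SD); mean_z at lag L averages
    the normalized value over all position pairs L apart. Raises on a
    degenerate (zero-SD) similarity structure.
    """
    if len(sequence) < max_lag + 1:
        raise AnalysisError(
            f"sequence of {len(sequence)} items cannot support max_lag {max_lag}"
        )
    idx = np.array([matrix.index(s) for s in sequence])
    distinct = np.unique(idx)
    sub = matrix.values[np.ix_(distinct, distinct)]
    iu = np.triu_indices(len(distinct), k=1)
    pool = sub[iu]
    mu = float(pool.mean())
    sd = float(pool.std(ddof=0))
    if sd == 0:
        raise AnalysisError("degenerate similarity structure: all-pairs SD is 0")

    lags, means, counts = [], [], []
    for lag in range(1, max_lag + 1):
        a, b = idx[:-lag], idx[lag:]
        vals = (matrix.values[a, b] - mu) / sd
        lags.append(lag)
        means.append(float(vals.mean()))
        counts.append(int(vals.size))
    return GradientResult(lags, means, counts)


def gradient_over_traces(
    traces: Sequence[WalkTrace], matrix: SimilarityMatrix, max_lag: int = 10
) -> GradientResult:
    """Per-trace gradients combined by pair-count-weighted averaging."""
    if not traces:
        raise AnalysisError("no traces supplied")
    per = [similarity_gradient(t.retrieved_ids, matrix, max_lag) for t in traces]
    lags = per[0].lags
    mean_z, n_pairs = [], []
    for j in range(len(lags)):
        ns = np.array([g.n_pairs[j] for g in per], dtype=float)
        ms = np.array([g.mean_z[j] for g in per])
        mean_z.append(float((ms * ns).sum() / ns.sum()))
        n_pairs.append(int(ns.sum()))
    return GradientResult(lags, mean_z, n_pairs)


def _csr_and_index(network: SemanticNetwork):
    nodes = network.node_ids
    pos = {node: i for i, node in enumerate(nodes)}
    n = len(nodes)
    rows, cols = [], []
    for u, v in network.graph.edges:
        rows += [pos[u], pos[v]]
        cols += [pos[v], pos[u]]
    adj = csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    return adj, pos


def min_path_lengths(
    network: SemanticNetwork,
    pairs: Sequence[tuple[str, str]],
    _chunk: int = 256,
) -> list[int | None]:
    """Breadth-first shortest path length for each node pair.

    Unreachable pairs are reported as ``None`` (missing), not infinity.
    Unknown node ids raise. Sources are deduplicated and distances computed
    per unique source in chunks, so repeated endpoints cost nothing extra.
    """
    adj, pos = _csr_and_index(network)
    for a, b in pairs:
        if a not in pos or b not in pos:
            missing = a if a not in pos else b
            raise AnalysisError(f"unknown node id {missing!r}")
    sources = sorted({pos[a] for a, _ in pairs})
    dist_rows: dict[int, np.ndarray] = {}
    for i in range(0, len(sources), _chunk):
        block = sources[i : i + _chunk]
        d = dijkstra(adj, directed=False, unweighted=True, indices=block)
        for src, row in zip(block, np.atleast_2d(d)):
            dist_rows[src] = row
    out: list[int | None] = []
    for a, b in pairs:
        d = dist_rows[pos[a]][pos[b]]
        out.append(None if np.isinf(d) else int(d))
    return out


def anova_oneway(groups: Sequence[Sequence[float]]):
    """Classical one-way ANOVA: F, df_between, df_within, p.

    F is the ratio of between-group to within-group mean squares with exact
    degrees of freedom; p from the F distribution's survival function.
    Identical data in all groups gives F = 0, p = 1. Requires >= 2 groups
    with >= 2 values each.
    """
    if len(groups) < 2:
        raise AnalysisError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise AnalysisError("every group needs at least 2 values")
    all_vals = np.concatenate(arrs)
    grand = all_vals.mean()
    ssb = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrs))
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    df1 = len(arrs) - 1
    df2 = int(all_vals.size) - len(arrs)
    if ssw == 0:
        f = 0.0 if ssb == 0 else float("inf")
    else:
        f = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return f, df1, df2, p


def iri_by_pathlength(
    traces: Sequence[WalkTrace],
    network: SemanticNetwork,
    max_length: int = 4,
    measure: str = "hop",
    aggregate: str = "run_mean",
) -> PathLengthResult:
    """Group log10 IRIs by the minimal path length of consecutive retrievals
    and test the path-length effect with a one-way ANOVA.

    For every consecutive retrieval pair (item k-1, item k), the IRI of item
    k is assigned to the group of the pair's minimal path length; lengths
    above ``max_length`` (default 4) are excluded. IRIs are log10-transformed
    to tame their heavy tails. With ``aggregate='run_mean'`` (default) each
    trace contributes one mean per length group — the ANOVA unit is the run;
    ``'pooled'`` enters every pair individually. Empty length groups are
    dropped with a warning and the degrees of freedom adjust accordingly.
    """
    if max_length < 2:
        raise AnalysisError("max_length must be >= 2")
    if not traces:
        raise AnalysisError("no traces supplied")

    pairs = []
    for t in traces:
        ids = t.retrieved_ids
        pairs.extend((ids[k - 1], ids[k]) for k in range(1, len(ids)))
    lengths = min_path_lengths(network, pairs)

    per_run: list[dict[int, list[float]]] = []
    li = 0
    for t in traces:
        iris = t.iris(measure)
        bucket: dict[int, list[float]] = {L: [] for L in range(1, max_length + 1)}
        for k in range(1, len(t.retrieved_ids)):
            L = lengths[li]
            li += 1
            if L is not None and 1 <= L <= max_length:
                bucket[L].append(float(np.log10(iris[k])))
        per_run.append(bucket)

    kept_lengths: list[int] = []
    groups: list[np.ndarray] = []
    for L in range(1, max_length + 1):
        if aggregate == "run_mean":
            vals = [float(np.mean(b[L])) for b in per_run if b[L]]
        elif aggregate == "pooled":
            vals = [v for b in per_run for v in b[L]]
        else:
            raise AnalysisError(f"unknown aggregate {aggregate!r}")
        if len(vals) < 2:
            logger.warning("path length %d has %d observation(s); dropped",
                           L, len(vals))
            continue
        kept_lengths.append(L)
        groups.append(np.asarray(vals))

    if len(groups) < 2:
        raise AnalysisError("fewer than 2 non-empty path-length groups")
    f, df1, df2, p = anova_oneway(groups)
    return PathLengthResult(kept_lengths, groups, f, df1, df2, p)
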