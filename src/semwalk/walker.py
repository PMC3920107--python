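"""Random walk with retrieval memory over a semantic network.

The model of category recall: a walker starts at a random node of the
network's largest component and hops, at each step, to a uniformly random
neighbor of its current node. On arriving at a node not yet retrieved, the
walker retrieves it with probability ``retrieval_prob`` (default 0.10) and
marks it; marked nodes are never retrieved again (retrieval memory — people
rarely repeat an item within a recall session). The walk ends after
``n_retrievals`` retrievals.

Two inter-response-interval (IRI) measures are recorded per retrieval:

* ``hop_iris[k]``   — number of hops strictly after retrieval k-1 up to and
  including the hop that lands on retrieval k (for k = 0, hops since the
  start node). Always >= 1: the start node is not eligible before the first
  hop.
* ``degree_iris[k]`` — the sum of node degrees over every node arrived at in
  that same span, retrieved node included (revisits counted each arrival):
  a proxy for the decision overhead of choosing among connections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from ._seeding import child_seeds
from .netbuild import SemanticNetwork


class WalkError(ValueError):
    """Raised when a walk cannot be run as configured."""


@dataclass(frozen=True)
class WalkConfig:
    retrieval_prob: float = 0.10
    n_retrievals: int = 400
    seed: int = 0
    max_steps: int | None = None  # None -> 10_000 * n_retrievals

    def __post_init__(self) -> None:
        if not (0 < self.retrieval_prob <= 1):
            raise WalkError("retrieval_prob must be in (0, 1]")
        if self.n_retrievals < 1:
            raise WalkError("n_retrievals must be >= 1")
        if self.max_steps is not None and self.max_steps < self.n_retrievals:
            raise WalkError("max_steps must be >= n_retrievals")

    @property
    def effective_max_steps(self) -> int:
        return self.max_steps if self.max_steps is not None else 10_000 * self.n_retrievals


@dataclass
class WalkTrace:
    """Ordered retrieval events of one walk."""

    retrieved_ids: list[str]
    hop_iris: list[int]
    degree_iris: list[int]
    steps_total: int
    config: WalkConfig
    network_provenance: str = "thresholded"
    truncated: bool = False

    def __post_init__(self) -> None:
        if not (len(self.retrieved_ids) == len(self.hop_iris) == len(self.degree_iris)):
            raise WalkError("trace event lists must have equal length")
        if len(set(self.retrieved_ids)) != len(self.retrieved_ids):
            raise WalkError("a retrieved node repeats within the trace")
        if sum(self.hop_iris) > self.steps_total:
            raise WalkError("hop IRIs exceed total steps")

    def iris(self, measure: str = "hop") -> np.ndarray:
        if measure == "hop":
            return np.asarray(self.hop_iris, dtype=float)
        if measure == "degree":
            return np.asarray(self.degree_iris, dtype=float)
        raise WalkError(f"unknown IRI measure {measure!r} (use 'hop' or 'degree')")


def _component_csr(network: SemanticNetwork):
    """CSR adjacency of the largest component, plus its node-id list."""
    comp = network.largest_component()
    pos = {node: i for i, node in enumerate(comp)}
    g = network.graph
    degrees = np.array([g.degree(node) for node in comp], dtype=np.int64)
    indptr = np.zeros(len(comp) + 1, dtype=np.int64)
    np.cumsum(degrees, out=indptr[1:])
    indices = np.empty(indptr[-1], dtype=np.int64)
    fill = indptr[:-1].copy()
    for node in comp:
        i = pos[node]
        for nbr in g.neighbors(node):
            indices[fill[i]] = pos[nbr]
            fill[i] += 1
    return comp, indptr, indices, degrees


def walk(network: SemanticNetwork, config: WalkConfig) -> WalkTrace:
    """Run one memory-bearing random walk; see module docstring for rules.

    The walk is confined to the largest connected component (a walker can
    never leave the component of its start node). Exceeding ``max_steps``
    returns the partial trace with ``truncated=True`` rather than failing.

    Raises
    ------
    WalkError
        If the largest component is smaller than ``n_retrievals``.
    """
    comp, indptr, indices, degrees = _component_csr(network)
    n = len(comp)
    if n < config.n_retrievals:
        raise WalkError(
            f"largest component has {n} nodes but {config.n_retrievals} "
            f"retrievals were requested"
        )
    if n < 2 or indptr[-1] == 0:
        raise WalkError("walk needs a component with at least one edge")

    rng = np.random.default_rng(config.seed)
    cur = int(rng.integers(n))
    marked = np.zeros(n, dtype=bool)

    retrieved: list[str] = []
    hop_iris: list[int] = []
    degree_iris: list[int] = []
    hops_in_span = 0
    deg_in_span = 0
    steps = 0
    max_steps = config.effective_max_steps
    p = config.retrieval_prob

    BUF = 8192
    u_move = rng.random(BUF)
    u_ret = rng.random(BUF)
    bi = 0

    while len(retrieved) < config.n_retrievals and steps < max_steps:
        if bi == BUF:
            u_move = rng.random(BUF)
            u_ret = rng.random(BUF)
            bi = 0
        start = indptr[cur]
        deg = indptr[cur + 1] - start
        cur = int(indices[start + int(u_move[bi] * deg)])
        steps += 1
        hops_in_span += 1
        deg_in_span += int(degrees[cur])
        if not marked[cur] and u_ret[bi] < p:
            marked[cur] = True
            retrieved.append(comp[cur])
            hop_iris.append(hops_in_span)
            degree_iris.append(deg_in_span)
            hops_in_span = 0
            deg_in_span = 0
        bi += 1

    return WalkTrace(
        retrieved_ids=retrieved,
        hop_iris=hop_iris,
        degree_iris=degree_iris,
        steps_total=steps,
        config=config,
        network_provenance=network.provenance,
        truncated=len(retrieved) < config.n_retrievals,
    )


def run_batch(
    network: SemanticNetwork, config: WalkConfig, n_runs: int
) -> list[WalkTrace]:
    """Run ``n_runs`` independent walks with seeds derived from config.seed.

    Per-run seeds come from a splittable seed sequence, so the batch is
    reproducible and order-independent: run k is identical whether run alone
    or within any larger batch sharing the master seed.
    """
    if n_runs < 1:
        raise WalkError("n_runs must be >= 1")
    seeds = child_seeds(config.seed, n_runs)
    return [walk(network, replace(config, seed=s)) for s in seeds]


# ---------------------------------------------------------------------------
# Trace I/O: JSONL, one event per line, header first
# ---------------------------------------------------------------------------

def write_trace(trace: WalkTrace, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        header = {
            "type": "header",
            "config": {
                "retrieval_prob": trace.config.retrieval_prob,
                "n_retrievals": trace.config.n_retrievals,
                "seed": trace.config.seed,
                "max_steps": trace.config.max_steps,
            },
            "network_provenance": trace.network_provenance,
            "steps_total": trace.steps_total,
            "truncated": trace.truncated,
        }
        fh.write(json.dumps(header) + "\n")
        for k, (node, h, d) in enumerate(
            zip(trace.retrieved_ids, trace.hop_iris, trace.degree_iris)
        ):
            fh.write(
                json.dumps({"k": k, "node": node, "hop_iri": h, "degree_iri": d})
                + "\n"
            )


def read_trace(path: str | Path) -> WalkTrace:
    with open(path, encoding="utf-8") as fh:
        header = json.loads(fh.readline())
        if header.get("type") != "header":
            raise WalkError(f"{path}: first line is not a trace header")
        ids, hops, degs = [], [], []
        for line in fh:
            if line.strip():
                ev = json.loads(line)
                ids.append(ev["node"])
                hops.append(int(ev["hop_iri"]))
                degs.append(int(ev["degree_iri"]))
    cfg = WalkConfig(**header["config"])
    return WalkTrace(
        retrieved_ids=ids,
        hop_iris=hops,
        degree_iris=degs,
        steps_total=int(header["steps_total"]),
        config=cfg,
        network_provenance=header.get("network_provenance", "thresholded"),
        truncated=bool(header.get("truncated", False)),
    )


def write_traces(traces: Sequence[WalkTrace], path: str | Path) -> None:
    """Write a batch of traces as run_000.jsonl ... in a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, trace in enumerate(traces):
        write_trace(trace, path / f"run_{i:03d}.jsonl")


def read_traces(path: str | Path) -> list[WalkTrace]:
    path = Path(path)
    files = sorted(path.glob("run_*.jsonl"))
    if not files:
        raise WalkError(f"no trace files (run_*.jsonl) in {path}")
    return [read_trace(f) for f in files]
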