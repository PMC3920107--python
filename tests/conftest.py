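"""Shared fixtures: small analytic objects and session-scoped simulations."""

from __future__ import annotations

import numpy as np
import pytest

from semwalk import (
    Direction,
    LemmaDistribution,
    SemanticSpaceSpec,
    SimilarityMatrix,
    TopicCorpusSpec,
    WalkConfig,
    build_network,
    find_threshold,
    generate_random_network,
    generate_semantic_space_network,
    generate_topic_corpus,
    normalize_corpus,
    pairwise_similarity,
    run_batch,
    scramble_network,
)

MASTER_SEED = 2014  # chosen once for the whole suite

# the study protocol's problem size: 20 walks x 400 retrievals at p = 0.10
FULL_WALKS = WalkConfig(retrieval_prob=0.10, n_retrievals=400,
                        seed=MASTER_SEED + 1)


@pytest.fixture(scope="session")
def full_control_network():
    """Size-matched uniform random control: 5131 nodes, 175,198 edges."""
    return generate_random_network(5131, 175_198, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def full_semantic_network():
    """Clustered scale-free concept-space network at the study size."""
    return generate_semantic_space_network(SemanticSpaceSpec(seed=MASTER_SEED))


@pytest.fixture(scope="session")
def full_control_traces(full_control_network):
    return run_batch(full_control_network, FULL_WALKS, 20)


@pytest.fixture(scope="session")
def full_semantic_traces(full_semantic_network):
    return run_batch(full_semantic_network, FULL_WALKS, 20)


def make_matrix(values, ids=None, direction=Direction.LOWER_IS_SIMILAR):
    values = np.asarray(values, dtype=float)
    if ids is None:
        ids = [f"d{i}" for i in range(values.shape[0])]
    return SimilarityMatrix(list(ids), values, direction)


def random_jsd_matrix(n, rng):
    """Random symmetric matrix with JSD-like values in (0, 1)."""
    v = rng.uniform(0.05, 0.95, size=(n, n))
    v = 0.5 * (v + v.T)
    np.fill_diagonal(v, 0.0)
    return make_matrix(v)


@pytest.fixture(scope="session")
def chain_matrix():
    """4 nodes, chain-structured: JSDs 0.1, 0.2, 0.3 along a path, 0.9 else."""
    v = np.full((4, 4), 0.9)
    np.fill_diagonal(v, 0.0)
    v[0, 1] = v[1, 0] = 0.1
    v[1, 2] = v[2, 1] = 0.2
    v[2, 3] = v[3, 2] = 0.3
    return make_matrix(v, ids=list("abcd"))


@pytest.fixture(scope="session")
def topic_corpus():
    """4 topics x 25 documents, the clustered-corpus reference condition."""
    return generate_topic_corpus(TopicCorpusSpec(seed=MASTER_SEED))


@pytest.fixture(scope="session")
def topic_distributions(topic_corpus):
    return normalize_corpus(topic_corpus, min_words=1, stopwords=set())


@pytest.fixture(scope="session")
def topic_matrix(topic_distributions):
    return pairwise_similarity(topic_distributions)


@pytest.fixture(scope="session")
def topic_network(topic_matrix):
    res = find_threshold(topic_matrix, coverage=0.9)
    return build_network(topic_matrix, res.threshold, res.retained_nodes)


@pytest.fixture(scope="session")
def topic_walks(topic_network):
    """20 walks of 60 retrievals on the thresholded topic network."""
    cfg = WalkConfig(retrieval_prob=0.1, n_retrievals=60, seed=MASTER_SEED + 1)
    return run_batch(topic_network, cfg, 20)


@pytest.fixture(scope="session")
def topic_scrambled(topic_network):
    return scramble_network(topic_network, seed=MASTER_SEED + 2)


@pytest.fixture(scope="session")
def topic_scrambled_walks(topic_scrambled):
    cfg = WalkConfig(retrieval_prob=0.1, n_retrievals=60, seed=MASTER_SEED + 3)
    return run_batch(topic_scrambled, cfg, 20)


def two_point(doc_id, p1, lemmas=("x", "y")):
    probs = {lemmas[0]: p1}
    if p1 < 1.0:
        probs[lemmas[1]] = 1.0 - p1
    return LemmaDistribution(doc_id, probs)
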