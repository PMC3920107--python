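"""Documents, lemma probability distributions, and Jensen-Shannon divergence.

A corpus here is a set of plain-text documents, one per concept (e.g. one
encyclopedia article per animal). Each document is reduced to a probability
distribution over lemmas — relative frequencies of content words after
stopword removal and inflection stripping — and concept similarity is the
Jensen-Shannon divergence (JSD) between those distributions:

    JSD(P || Q) = 1/2 D(P || M) + 1/2 D(Q || M),   M = (P + Q) / 2

where D is the Kullback-Leibler divergence. Computed with base-2 logarithms
the JSD is exactly bounded in [0, 1]: 0 for identical distributions, 1 for
disjoint supports. Lower JSD means more similar documents.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[a-z][a-z']*")


class CorpusError(ValueError):
    """Raised for invalid or degenerate corpus inputs."""


@dataclass(frozen=True)
class Document:
    """One raw document: a unique id and its text."""

    doc_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusError("doc_id must be non-empty")
        if len(self.text) < 1:
            raise CorpusError(f"document {self.doc_id!r} has empty text")


@dataclass
class LemmaDistribution:
    """Normalized probability distribution over lemmas for one document.

    All stored probabilities are strictly positive (zero-mass lemmas are
    omitted) and sum to 1 within 1e-9.
    """

    doc_id: str
    probs: dict[str, float]

    def __post_init__(self) -> None:
        if not self.probs:
            raise CorpusError(f"distribution {self.doc_id!r} has no lemmas")
        total = math.fsum(self.probs.values())
        if abs(total - 1.0) > 1e-9:
            raise CorpusError(
                f"distribution {self.doc_id!r} sums to {total!r}, not 1"
            )
        if any(p <= 0 for p in self.probs.values()):
            raise CorpusError(
                f"distribution {self.doc_id!r} has non-positive probabilities"
            )

    def support(self) -> set[str]:
        return set(self.probs)


class Direction(str, Enum):
    """Whether smaller or larger matrix values mean more similar documents."""

    LOWER_IS_SIMILAR = "lower_is_similar"
    HIGHER_IS_SIMILAR = "higher_is_similar"


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity/divergence scores for a document set."""

    doc_ids: list[str]
    values: np.ndarray
    direction: Direction = Direction.LOWER_IS_SIMILAR
    measure: str = "jsd"
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.doc_ids)
        if len(set(self.doc_ids)) != n:
            dupes = sorted({d for d in self.doc_ids if self.doc_ids.count(d) > 1})
            raise CorpusError(f"duplicate doc_ids: {dupes}")
        if self.values.shape != (n, n):
            raise CorpusError(
                f"matrix shape {self.values.shape} does not match {n} doc_ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise CorpusError("similarity matrix is not symmetric within 1e-12")

    @property
    def n(self) -> int:
        return len(self.doc_ids)

    def index(self, doc_id: str) -> int:
        try:
            return self.doc_ids.index(doc_id)
        except ValueError:
            raise KeyError(f"unknown doc_id {doc_id!r}") from None

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle values, i < j, as a flat array."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# Tokenization and lemmatization
# ---------------------------------------------------------------------------

def tokenize(text: str) -> list[str]:
    """Lowercase and extract alphabetic word tokens (apostrophes kept)."""
    return _TOKEN_RE.findall(text.lower())


def default_lemmatizer(token: str) -> str:
    """Rule-based English inflection stripper.

    Removes common inflectional suffixes (plural -s/-es/-ies, -ing, -ed)
    with minimal-stem guards. Deliberately conservative: it maps inflected
    variants of a word onto a shared form, it does not attempt derivational
    morphology or dictionary lookup. Any token normalizer with the same
    ``str -> str`` signature can be supplied instead.
    """
    t = token.strip("'")
    if not t:
        return token
    if len(t) > 4 and t.endswith("ies"):
        return t[:-3] + "y"
    if len(t) > 3 and t.endswith("sses"):
        return t[:-2]
    if len(t) > 3 and t.endswith("es") and not t.endswith(("ses", "oes")):
        # e.g. "foxes" -> "fox"; keep final e only when stem would be too short
        stem = t[:-2]
        if stem.endswith(("x", "ch", "sh", "z")):
            return stem
        return t[:-1]
    if len(t) > 3 and t.endswith("s") and not t.endswith(("ss", "us", "is")):
        return t[:-1]
    if len(t) > 5 and t.endswith("ing"):
        stem = t[:-3]
        if len(stem) > 2 and stem[-1] == stem[-2]:  # hopping -> hop
            return stem[:-1]
        return stem
    if len(t) > 4 and t.endswith("ed"):
        stem = t[:-2]
        if len(stem) > 2 and stem[-1] == stem[-2]:
            return stem[:-1]
        return stem
    return t


def load_default_stopwords() -> set[str]:
    """Load the packaged English function-word list."""
    text = (
        resources.files("semwalk").joinpath("data/stopwords.txt").read_text("utf-8")
    )
    return _parse_stopwords(text.splitlines())


def load_stopwords(path: str | Path) -> set[str]:
    """Load a user stopword file: one word per line, '#' comments ignored."""
    return _parse_stopwords(Path(path).read_text("utf-8").splitlines())


def _parse_stopwords(lines: Iterable[str]) -> set[str]:
    out = set()
    for line in lines:
        word = line.split("#", 1)[0].strip().lower()
        if word:
            out.add(word)
    return out


# ---------------------------------------------------------------------------
# Corpus normalization
# ---------------------------------------------------------------------------

def normalize_corpus(
    documents: Sequence[Document],
    min_words: int = 500,
    stopwords: set[str] | None = None,
    lemmatizer: Callable[[str], str] = default_lemmatizer,
) -> list[LemmaDistribution]:
    """Convert documents to lemma probability distributions.

    Tokenizes, drops documents with fewer than ``min_words`` tokens (counted
    before stopword removal, matching word counts of running text), removes
    stopwords, lemmatizes, and normalizes lemma frequencies to probabilities.

    Parameters
    ----------
    documents:
        Corpus with unique ``doc_id`` values.
    min_words:
        Minimum token count for a document to be kept (default 500).
    stopwords:
        Function words to discard; ``None`` uses the packaged list. Pass an
        empty set to keep everything.
    lemmatizer:
        Token normalizer; tokens on which it raises are skipped (counted and
        logged), tokens it maps to the empty string are skipped likewise.

    Raises
    ------
    CorpusError
        If ``min_words < 1``, doc_ids repeat, or no document survives
        filtering ("no usable documents").
    """
    if min_words < 1:
        raise CorpusError("min_words must be >= 1")
    ids = [d.doc_id for d in documents]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise CorpusError(f"duplicate doc_ids: {dupes}")
    if stopwords is None:
        stopwords = load_default_stopwords()

    out: list[LemmaDistribution] = []
    dropped: list[str] = []
    n_lemma_failures = 0
    for doc in documents:
        tokens = tokenize(doc.text)
        if len(tokens) < min_words:
            dropped.append(doc.doc_id)
            continue
        counts: dict[str, int] = {}
        for tok in tokens:
            if tok in stopwords:
                continue
            try:
                lemma = lemmatizer(tok)
            except Exception:
                n_lemma_failures += 1
                continue
            if not lemma:
                n_lemma_failures += 1
                continue
            counts[lemma] = counts.get(lemma, 0) + 1
        if not counts:
            dropped.append(doc.doc_id)
            continue
        total = sum(counts.values())
        out.append(
            LemmaDistribution(doc.doc_id, {w: c / total for w, c in counts.items()})
        )
    if dropped:
        logger.info(
            "dropped %d document(s) below %d words or with no content tokens: %s",
            len(dropped), min_words, ", ".join(dropped[:10]),
        )
    if n_lemma_failures:
        logger.info("skipped %d token(s) the lemmatizer could not handle",
                    n_lemma_failures)
    if not out:
        raise CorpusError("no usable documents after filtering")
    return out


# ---------------------------------------------------------------------------
# Divergences
# ---------------------------------------------------------------------------

def _aligned(p: LemmaDistribution, q: LemmaDistribution):
    vocab = sorted(p.support() | q.support())
    pv = np.array([p.probs.get(w, 0.0) for w in vocab])
    qv = np.array([q.probs.get(w, 0.0) for w in vocab])
    return pv, qv


def kl_divergence(
    p: LemmaDistribution, q: LemmaDistribution, log_base: float = math.e
) -> float:
    """Kullback-Leibler divergence D(P || Q) = sum_i p_i log(p_i / q_i).

    Returns ``inf`` when Q assigns zero mass to a lemma with positive P mass
    (this is the divergence's value there, not an error). 0 iff P == Q.
    """
    pv, qv = _aligned(p, q)
    return _kl_arrays(pv, qv, log_base)


def _kl_arrays(pv: np.ndarray, qv: np.ndarray, log_base: float) -> float:
    mask = pv > 0
    if np.any(qv[mask] == 0):
        return math.inf
    val = float(np.sum(pv[mask] * np.log(pv[mask] / qv[mask])))
    return val / math.log(log_base)


def jsd(p: LemmaDistribution, q: LemmaDistribution) -> float:
    """Jensen-Shannon divergence, base-2 logs, bounded in [0, 1].

    JSD(P||Q) = 1/2 D(P||M) + 1/2 D(Q||M) with M = (P+Q)/2. Symmetric and
    always finite: M covers the support of both arguments.
    """
    pv, qv = _aligned(p, q)
    return _jsd_arrays(pv, qv)


def _jsd_arrays(pv: np.ndarray, qv: np.ndarray) -> float:
    mv = 0.5 * (pv + qv)
    val = 0.5 * _kl_arrays(pv, mv, 2.0) + 0.5 * _kl_arrays(qv, mv, 2.0)
    # guard fp drift just outside the theoretical bounds
    return float(min(max(val, 0.0), 1.0))


def pairwise_similarity(
    distributions: Sequence[LemmaDistribution],
) -> SimilarityMatrix:
    """All-pairs JSD matrix (direction: lower is more similar, diagonal 0)."""
    if len(distributions) < 2:
        raise CorpusError("need at least 2 distributions")
    ids = [d.doc_id for d in distributions]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise CorpusError(f"duplicate doc_ids: {dupes}")

    vocab = sorted(set().union(*(d.support() for d in distributions)))
    col = {w: j for j, w in enumerate(vocab)}
    mat = np.zeros((len(ids), len(vocab)))
    for i, d in enumerate(distributions):
        for w, pr in d.probs.items():
            mat[i, col[w]] = pr

    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = _jsd_arrays(mat[i], mat[j])
            values[i, j] = values[j, i] = v
    return SimilarityMatrix(ids, values, Direction.LOWER_IS_SIMILAR, "jsd")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_corpus_dir(path: str | Path) -> list[Document]:
    """Read a directory of UTF-8 ``.txt`` files; filename stem = doc_id."""
    path = Path(path)
    docs = [
        Document(f.stem, f.read_text("utf-8"))
        for f in sorted(path.glob("*.txt"))
    ]
    if not docs:
        raise CorpusError(f"no .txt documents found in {path}")
    return docs


def read_corpus_jsonl(path: str | Path) -> list[Document]:
    """Read a JSONL corpus with fields ``doc_id`` and ``text``."""
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                docs.append(Document(rec["doc_id"], rec["text"]))
    if not docs:
        raise CorpusError(f"no documents found in {path}")
    return docs


def write_corpus_dir(documents: Sequence[Document], path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for doc in documents:
        (path / f"{doc.doc_id}.txt").write_text(doc.text, "utf-8")


def write_distributions(
    distributions: Sequence[LemmaDistribution], path: str | Path
) -> None:
    """Write distributions as TSV: doc_id <TAB> lemma <TAB> prob."""
    rows = [
        (d.doc_id, lemma, prob)
        for d in distributions
        for lemma, prob in sorted(d.probs.items())
    ]
    pd.DataFrame(rows, columns=["doc_id", "lemma", "prob"]).to_csv(
        path, sep="\t", index=False
    )


def read_distributions(path: str | Path) -> list[LemmaDistribution]:
    df = pd.read_csv(path, sep="\t", dtype={"doc_id": str, "lemma": str})
    out = []
    for doc_id, grp in df.groupby("doc_id", sort=False):
        probs = dict(zip(grp["lemma"], grp["prob"].astype(float)))
        total = math.fsum(probs.values())
        # renormalize away TSV rounding so invariants hold after round-trip
        out.append(LemmaDistribution(str(doc_id), {w: p / total for w, p in probs.items()}))
    return out


def write_similarity(matrix: SimilarityMatrix, path: str | Path) -> None:
    """Write the matrix as TSV (doc_ids as header row/column) + sidecar JSON."""
    path = Path(path)
    df = pd.DataFrame(matrix.values, index=matrix.doc_ids, columns=matrix.doc_ids)
    df.to_csv(path, sep="\t", index_label="doc_id", float_format="%.12g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps(
            {
                "direction": matrix.direction.value,
                "measure": matrix.measure,
                "parameters": matrix.parameters,
            },
            indent=2,
        ),
        "utf-8",
    )


def read_similarity(path: str | Path) -> SimilarityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    values = 0.5 * (values + values.T)  # undo asymmetric rounding from text round-trip
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    direction, measure, params = Direction.LOWER_IS_SIMILAR, "jsd", {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text("utf-8"))
        direction = Direction(meta.get("direction", direction.value))
        measure = meta.get("measure", measure)
        params = meta.get("parameters", {})
    return SimilarityMatrix(
        [str(c) for c in df.columns], values, direction, measure, params
    )
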