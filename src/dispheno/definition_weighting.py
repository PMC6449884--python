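"""TF-IDF definition similarity as DAG edge weights.

Each term's free-text definition is treated as a document.  With
tf(p, t) = n_p / |t| (word count over document length) and
idf(p) = ln(|T| / df(p)) over the corpus of all term definitions, every
``is_a`` edge (child, parent) is scored with the cosine similarity of the
two endpoints' tf-idf vectors, producing a weighted DAG (WDAG).  The
weight product along a path later attenuates term similarity between
textually unrelated terms.

The tf-idf here is deliberately the plain two-pass formula (no smoothing,
no +1 on the idf): a word occurring in every definition carries weight 0
exactly, and the examples in the test suite are hand-checkable.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

from .ontology_core import OntologyGraph, Term

__all__ = [
    "STOPWORDS",
    "WeightedDag",
    "tokenize_definition",
    "tfidf_vectors",
    "build_wdag",
    "unit_wdag",
    "cosine",
]

#: Small fixed English stop-word list (function words common in phenotype
#: definitions); toggleable in the tokenizer.
STOPWORDS: frozenset[str] = frozenset(
    """a an and are as at be been between both but by during for from has have
    in into is it its may more most no not of on or other some such than that
    the their this to usually when which with within without""".split()
)

_TOKEN = re.compile(r"[a-z0-9]+")


@dataclass
class WeightedDag:
    """The ontology DAG with a cosine-of-definitions weight on every edge."""

    base: OntologyGraph
    edge_weight: dict[tuple[str, str], float] = field(default_factory=dict)

    def weight(self, child: str, parent: str) -> float:
        return self.edge_weight[(child, parent)]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("child_id\tparent_id\tweight\n")
            for (c, p) in sorted(self.edge_weight):
                fh.write(f"{c}\t{p}\t{self.edge_weight[(c, p)]!r}\n")

    @classmethod
    def from_tsv(cls, base: OntologyGraph, path: str | Path) -> "WeightedDag":
        weights: dict[tuple[str, str], float] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("child_id", "#")):
                    continue
                c, p, w = line.split("\t")
                weights[(c, p)] = float(w)
        missing = set(base.edges) - set(weights)
        if missing:
            raise ValueError(f"edge-weight cache missing {len(missing)} edges")
        return cls(base=base, edge_weight=weights)


def tokenize_definition(term: Term, use_stopwords: bool = True) -> list[str]:
    """Lowercased, punctuation-stripped, stop-word-filtered tokens.

    Falls back to the term name plus synonyms when the definition is empty,
    so nameless placeholder terms are the only ones that tokenize to [].
    """
    text = term.definition.strip()
    if not text:
        text = " ".join((term.name, *term.synonyms))
    tokens = _TOKEN.findall(text.lower())
    if use_stopwords:
        tokens = [t for t in tokens if t not in STOPWORDS]
    return tokens


def tfidf_vectors(
    ontology: OntologyGraph, use_stopwords: bool = True
) -> dict[str, dict[str, float]]:
    """Sparse tf-idf vector per term over the corpus of all definitions.

    Component for word p in term t: (n_p / |t|) * ln(|T| / df(p)).  Exact
    zeros (words present in every document) are not materialized.
    """
    docs = {
        tid: tokenize_definition(term, use_stopwords)
        for tid, term in ontology.terms.items()
    }
    n_docs = len(docs)
    df: dict[str, int] = {}
    for tokens in docs.values():
        for word in set(tokens):
            df[word] = df.get(word, 0) + 1
    idf = {w: math.log(n_docs / d) for w, d in df.items()}

    vectors: dict[str, dict[str, float]] = {}
    for tid, tokens in docs.items():
        vec: dict[str, float] = {}
        if tokens:
            length = len(tokens)
            counts: dict[str, int] = {}
            for w in tokens:
                counts[w] = counts.get(w, 0) + 1
            for w, n in counts.items():
                weight = (n / length) * idf[w]
                if weight != 0.0:
                    vec[w] = weight
        vectors[tid] = vec
    return vectors


def cosine(u: dict[str, float], v: dict[str, float]) -> float:
    """Cosine similarity of two sparse vectors; 0 when either has no mass."""
    if not u or not v:
        return 0.0
    if len(v) < len(u):
        u, v = v, u
    dot = sum(w * v[k] for k, w in u.items() if k in v)
    nu = math.sqrt(sum(w * w for w in u.values()))
    nv = math.sqrt(sum(w * w for w in v.values()))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return dot / (nu * nv)


def build_wdag(ontology: OntologyGraph, use_stopwords: bool = True) -> WeightedDag:
    """Score every ``is_a`` edge with the definition cosine of its endpoints.

    An endpoint with an empty tf-idf vector gets the neutral weight 1.0: a
    zero there would annihilate every path through the term in the
    downstream weight product, which no missing definition should do.
    """
    vectors = tfidf_vectors(ontology, use_stopwords)
    weights: dict[tuple[str, str], float] = {}
    for child, parent in ontology.graph.edges():
        u, v = vectors[child], vectors[parent]
        if not u or not v:
            w = 1.0
        else:
            w = min(1.0, max(0.0, cosine(u, v)))
        weights[(child, parent)] = w
    return WeightedDag(base=ontology, edge_weight=weights)


def unit_wdag(ontology: OntologyGraph) -> WeightedDag:
    """All edge weights 1.0 — the Weight-off ablation (plain DAG)."""
    return WeightedDag(
        base=ontology,
        edge_weight={e: 1.0 for e in ontology.graph.edges()},
    )
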