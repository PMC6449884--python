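"""Dual-source information content.

Each ontology term gets an information content from the gene corpus,
IC_gene(t) = ln(G / G_t), and one from the disease corpus,
IC_disease(t) = ln(D / D_t), where G (D) is the number of annotation
units and G_t (D_t) the number of units annotating t or any of its
descendants (annotations are propagated up the hierarchy before
counting — the true-path rule).  The two are blended with a weighting
coefficient w in [0, 1]:

    IC(t) = w * IC_gene(t) + (1 - w) * IC_disease(t)

Terms never reached by any annotation of a source are assigned that
source's maximum observed IC — they are treated as maximally specific,
keeping every downstream product finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .ontology_core import AnnotationCorpus, AnnotationError, OntologyGraph

__all__ = ["ICTable", "propagated_counts", "compute_ic", "source_ic"]


@dataclass
class ICTable:
    """Per-term information content (nats) from both sources and their blend."""

    ic_gene: dict[str, float]
    ic_disease: dict[str, float]
    w: float
    ic: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ic:
            w = self.w
            self.ic = {
                t: w * self.ic_gene[t] + (1.0 - w) * self.ic_disease[t]
                for t in self.ic_gene
            }

    def __getitem__(self, term_id: str) -> float:
        return self.ic[term_id]

    # -- TSV cache -------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# w={self.w!r}\n")
            fh.write("term_id\tic_gene\tic_disease\tic\n")
            for t in sorted(self.ic):
                fh.write(f"{t}\t{self.ic_gene[t]!r}\t{self.ic_disease[t]!r}\t{self.ic[t]!r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ICTable":
        ic_gene: dict[str, float] = {}
        ic_disease: dict[str, float] = {}
        ic: dict[str, float] = {}
        w = 0.5
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("# w="):
                    w = float(line[4:])
                    continue
                if not line or line.startswith(("term_id", "#")):
                    continue
                t, g, d, c = line.split("\t")
                ic_gene[t], ic_disease[t], ic[t] = float(g), float(d), float(c)
        return cls(ic_gene=ic_gene, ic_disease=ic_disease, w=w, ic=ic)


def propagated_counts(
    ontology: OntologyGraph, unit_to_terms: dict[str, frozenset[str]]
) -> dict[str, int]:
    """Unit-distinct annotation counts after true-path propagation.

    count(t) = number of units annotated to t or to any descendant of t;
    a unit annotated twice below t still counts once.  count(root) equals
    the number of units with at least one annotation.
    """
    counts = dict.fromkeys(ontology.terms, 0)
    for terms in unit_to_terms.values():
        for t in ontology.closure(terms):
            counts[t] += 1
    return counts


def _ic_from_counts(counts: dict[str, int], total: int) -> dict[str, float]:
    ic = {}
    observed_max = 0.0
    for t, c in counts.items():
        if c > 0:
            v = math.log(total / c)
            ic[t] = v
            if v > observed_max:
                observed_max = v
    for t, c in counts.items():
        if c == 0:
            ic[t] = observed_max
    return ic


def source_ic(
    ontology: OntologyGraph, unit_to_terms: dict[str, frozenset[str]]
) -> dict[str, float]:
    """Single-source IC: ln(total units / propagated count), zero-count
    terms pinned at the maximum observed IC of the source."""
    counts = propagated_counts(ontology, unit_to_terms)
    total = counts[ontology.root]
    if total == 0:
        raise AnnotationError("annotation corpus is empty for this source")
    return _ic_from_counts(counts, total)


def compute_ic(
    ontology: OntologyGraph, corpus: AnnotationCorpus, w: float = 0.5
) -> ICTable:
    """Blend gene- and disease-derived IC with weighting coefficient ``w``.

    ``w = 1`` reproduces gene-only IC, ``w = 0`` disease-only IC; the blend
    is linear in ``w`` term by term.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"w must lie in [0, 1], got {w}")
    ic_gene = source_ic(ontology, corpus.gene_to_terms)
    ic_disease = source_ic(ontology, corpus.disease_to_terms)
    return ICTable(ic_gene=ic_gene, ic_disease=ic_disease, w=w)
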