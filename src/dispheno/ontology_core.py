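"""Ontology and annotation parsing.

Reads an OBO ontology (``is_a`` hierarchy only) into a validated rooted DAG
and the two annotation TSV dialects used by the Human Phenotype Ontology
project (``genes_to_phenotype.txt`` and ``phenotype.hpoa``) into an
:class:`AnnotationCorpus`.  Everything downstream — information content,
edge weighting, term and set similarity — walks these two structures.

Conventions
-----------
* Edges are stored child -> parent, so "ancestors" are reachable by
  following edges forward.
* Obsolete terms are dropped at parse time; alternate ids are kept in a
  resolution map so stale annotation rows can still be used.
* Only ``is_a`` relationships are kept: the hierarchy is a pure subclass
  DAG, as in the HPO.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet

logger = logging.getLogger("dispheno")

__all__ = [
    "Term",
    "OntologyGraph",
    "AnnotationCorpus",
    "OntologyError",
    "AnnotationError",
    "parse_obo",
    "parse_annotations",
    "parse_frequency",
    "ancestors",
    "most_depth",
    "FREQUENCY_MODIFIERS",
    "HPO_PHENOTYPIC_ABNORMALITY",
]


class OntologyError(ValueError):
    """Structural problem in an ontology file (cycle, no root, unknown id)."""


class AnnotationError(ValueError):
    """Malformed or empty annotation input."""


#: HPO frequency-modifier terms mapped to midpoint probabilities.
FREQUENCY_MODIFIERS: dict[str, float] = {
    "HP:0040280": 1.0,    # Obligate
    "HP:0040281": 0.895,  # Very frequent (80-99%)
    "HP:0040282": 0.545,  # Frequent (30-79%)
    "HP:0040283": 0.17,   # Occasional (5-29%)
    "HP:0040284": 0.025,  # Very rare (1-4%)
    "HP:0040285": 0.0,    # Excluded
}

#: Root of the clinically used HPO subtree; preferred as default root when present.
HPO_PHENOTYPIC_ABNORMALITY = "HP:0000118"

_QUOTED = re.compile(r'"((?:[^"\\]|\\.)*)"')


@dataclass(frozen=True)
class Term:
    """A single ontology term: accession id, label, free-text definition."""

    id: str
    name: str = ""
    definition: str = ""
    synonyms: tuple[str, ...] = ()


@dataclass
class OntologyGraph:
    """A rooted ``is_a`` DAG of terms.

    ``graph`` holds edges child -> parent; ``alt_ids`` maps secondary
    accessions to their primary term id.
    """

    terms: dict[str, Term]
    graph: nx.DiGraph
    root: str
    alt_ids: dict[str, str] = field(default_factory=dict)
    _anc_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    # -- basic queries -------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def edges(self) -> set[tuple[str, str]]:
        """All (child, parent) pairs."""
        return set(self.graph.edges())

    def parents(self, term_id: str) -> set[str]:
        self._check(term_id)
        return set(self.graph.successors(term_id))

    def children(self, term_id: str) -> set[str]:
        self._check(term_id)
        return set(self.graph.predecessors(term_id))

    def leaves(self) -> set[str]:
        return {t for t in self.terms if self.graph.in_degree(t) == 0}

    def resolve(self, term_id: str) -> str | None:
        """Map a possibly-alternate id to its primary id, or None if unknown."""
        if term_id in self.terms:
            return term_id
        return self.alt_ids.get(term_id)

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Transitive parents of ``term_id`` (excluding itself)."""
        self._check(term_id)
        cached = self._anc_cache.get(term_id)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, term_id))
            self._anc_cache[term_id] = cached
        return cached

    def descendants(self, term_id: str) -> frozenset[str]:
        self._check(term_id)
        return frozenset(nx.ancestors(self.graph, term_id))

    def closure(self, term_ids) -> frozenset[str]:
        """Terms plus all their ancestors (true-path propagation)."""
        out: set[str] = set()
        for t in term_ids:
            out.add(t)
            out |= self.ancestors(t)
        return frozenset(out)

    def most_depth(self) -> int:
        """Longest directed path (in edges) from any leaf to the root."""
        if len(self.terms) <= 1:
            return 0
        return int(nx.dag_longest_path_length(self.graph))

    # -- validation ----------------------------------------------------

    def _check(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise OntologyError(f"unknown term id: {term_id!r}")

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise OntologyError(f"ontology contains a cycle: {cycle}")
        for u, v in self.graph.edges():
            if u == v:
                raise OntologyError(f"self-edge on {u}")
        for t in self.terms:
            if t != self.root and self.root not in self.ancestors(t):
                raise OntologyError(f"term {t} cannot reach root {self.root}")


# ---------------------------------------------------------------------------
# OBO parsing
# ---------------------------------------------------------------------------


def _unquote(raw: str) -> str:
    """Extract the quoted payload of an OBO ``def:``/``synonym:`` value."""
    m = _QUOTED.search(raw)
    return m.group(1) if m else raw.strip()


def parse_obo(path: str | Path, root: str | None = None) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 file into a validated :class:`OntologyGraph`.

    Obsolete terms are excluded and only ``is_a`` edges are kept.  If
    ``root`` is given, the graph is restricted to that term and its
    descendants.  Otherwise, the HPO "Phenotypic abnormality" subtree is
    used when present (the clinically meaningful subgraph); failing that,
    the unique parentless term is taken as root, and multiple apexes are
    a hard error.
    """
    multigraph = obonet.read_obo(str(path))
    if len(multigraph) == 0:
        raise OntologyError(f"no [Term] stanzas found in {path}")

    g = nx.DiGraph()
    terms: dict[str, Term] = {}
    alt_ids: dict[str, str] = {}
    for node, data in multigraph.nodes(data=True):
        definition = _unquote(data.get("def", "")) if data.get("def") else ""
        synonyms = tuple(_unquote(s) for s in data.get("synonym", ()))
        terms[node] = Term(
            id=node,
            name=data.get("name", ""),
            definition=definition,
            synonyms=synonyms,
        )
        g.add_node(node)
        for alt in data.get("alt_id", ()):
            alt_ids[alt] = node
    for child, parent, key in multigraph.edges(keys=True):
        if key != "is_a":
            continue
        if child == parent:
            raise OntologyError(f"self-edge on {child}")
        g.add_edge(child, parent)

    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise OntologyError(f"ontology contains a cycle: {cycle}")

    if root is None and HPO_PHENOTYPIC_ABNORMALITY in g:
        root = HPO_PHENOTYPIC_ABNORMALITY
        logger.info("restricting to the Phenotypic abnormality subtree (%s)", root)

    if root is not None:
        if root not in g:
            raise OntologyError(f"requested root {root!r} not in ontology")
        # in child->parent orientation the subtree below root is nx.ancestors
        keep = set(nx.ancestors(g, root)) | {root}
        g = g.subgraph(keep).copy()
        terms = {t: terms[t] for t in keep}
        alt_ids = {a: p for a, p in alt_ids.items() if p in keep}
    else:
        apexes = sorted(t for t in g if g.out_degree(t) == 0)
        if len(apexes) != 1:
            raise OntologyError(
                "cannot auto-detect root: parentless terms " + ", ".join(apexes)
            )
        root = apexes[0]

    onto = OntologyGraph(terms=terms, graph=g, root=root, alt_ids=alt_ids)
    onto.validate()
    logger.info("parsed ontology: %d terms, %d is_a edges, root %s",
                len(terms), g.number_of_edges(), root)
    return onto


# ---------------------------------------------------------------------------
# Annotation parsing
# ---------------------------------------------------------------------------


@dataclass
class AnnotationCorpus:
    """Gene->terms and disease->terms maps with per-(disease, term) frequency.

    ``frequency`` holds the penetrance probability of a phenotype given its
    disease; absent entries default to 1.0 (the phenotype is always shown).
    """

    gene_to_terms: dict[str, frozenset[str]]
    disease_to_terms: dict[str, frozenset[str]]
    frequency: dict[tuple[str, str], float] = field(default_factory=dict)
    dropped_rows: dict[str, int] = field(default_factory=dict)

    def units(self, source: str) -> dict[str, frozenset[str]]:
        """Annotation units for ``source`` in {'gene', 'disease', 'union'}."""
        if source == "gene":
            return self.gene_to_terms
        if source == "disease":
            return self.disease_to_terms
        if source == "union":
            merged: dict[str, frozenset[str]] = {}
            for k, v in self.gene_to_terms.items():
                merged[f"gene:{k}"] = v
            for k, v in self.disease_to_terms.items():
                merged[f"disease:{k}"] = v
            return merged
        raise AnnotationError(f"unknown annotation source {source!r}")

    def freq(self, disease: str, term: str) -> float:
        return self.frequency.get((disease, term), 1.0)


_FRACTION = re.compile(r"^\s*(\d+)\s*/\s*(\d+)\s*$")
_PERCENT = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*%\s*$")


def parse_frequency(cell: str | float | None) -> float:
    """Convert an hpoa frequency cell to a probability in [0, 1].

    Accepts HPO frequency-modifier term ids (mapped to midpoints), ``n/m``
    fractions, percentages, bare floats; an empty cell means 1.0.
    """
    if cell is None:
        return 1.0
    if isinstance(cell, float):
        if math.isnan(cell):
            return 1.0
        value = cell
    else:
        text = str(cell).strip()
        if not text:
            return 1.0
        if text in FREQUENCY_MODIFIERS:
            return FREQUENCY_MODIFIERS[text]
        if m := _FRACTION.match(text):
            num, den = int(m.group(1)), int(m.group(2))
            if den == 0:
                raise AnnotationError(f"zero denominator in frequency {text!r}")
            value = num / den
        elif m := _PERCENT.match(text):
            value = float(m.group(1)) / 100.0
        else:
            try:
                value = float(text)
            except ValueError:
                raise AnnotationError(f"unparseable frequency cell {text!r}") from None
    if not 0.0 <= value <= 1.0:
        raise AnnotationError(f"frequency {value} outside [0, 1]")
    return value


def _read_tsv_rows(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Read a TSV with an optional '#'-prefixed header and comment lines."""
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if header is None:
                if line.startswith("#") and "\t" not in line:
                    continue  # metadata comment, e.g. "#description: ..."
                # first tabbed line is the header, possibly '#'-prefixed
                header = [c.strip().lower() for c in line.lstrip("#").split("\t")]
                continue
            if line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    if header is None:
        raise AnnotationError(f"{path}: empty file")
    return header, rows


def _column(header: list[str], candidates: list[str], path) -> int:
    for cand in candidates:
        if cand in header:
            return header.index(cand)
    raise AnnotationError(
        f"{path}: missing mandatory column (expected one of {candidates}; got {header})"
    )


def parse_annotations(
    gene_path: str | Path,
    disease_path: str | Path,
    ontology: OntologyGraph,
) -> AnnotationCorpus:
    """Parse gene->phenotype and disease->phenotype TSVs into a corpus.

    Follows the ``genes_to_phenotype.txt`` and ``phenotype.hpoa`` column
    dialects.  Rows whose term id is unknown to the ontology (after alt-id
    resolution) are dropped and counted; frequency cells are converted to
    probabilities with :func:`parse_frequency`.
    """
    gene_header, gene_rows = _read_tsv_rows(gene_path)
    g_sym = _column(gene_header, ["gene_symbol", "entrez-gene-symbol", "gene-symbol"], gene_path)
    g_hpo = _column(gene_header, ["hpo_id", "hpo-term-id", "hpo_term_id"], gene_path)

    gene_to_terms: dict[str, set[str]] = {}
    dropped_gene = 0
    for row in gene_rows:
        if len(row) <= max(g_sym, g_hpo):
            dropped_gene += 1
            continue
        term = ontology.resolve(row[g_hpo].strip())
        if term is None:
            dropped_gene += 1
            continue
        gene_to_terms.setdefault(row[g_sym].strip(), set()).add(term)

    dis_header, dis_rows = _read_tsv_rows(disease_path)
    d_id = _column(dis_header, ["database_id", "databaseid", "disease_id", "#database_id"], disease_path)
    d_hpo = _column(dis_header, ["hpo_id", "hpo-term-id", "hpo_term_id"], disease_path)
    d_freq = None
    for cand in ("frequency",):
        if cand in dis_header:
            d_freq = dis_header.index(cand)

    disease_to_terms: dict[str, set[str]] = {}
    frequency: dict[tuple[str, str], float] = {}
    dropped_dis = 0
    for row in dis_rows:
        if len(row) <= max(d_id, d_hpo):
            dropped_dis += 1
            continue
        term = ontology.resolve(row[d_hpo].strip())
        if term is None:
            dropped_dis += 1
            continue
        disease = row[d_id].strip()
        disease_to_terms.setdefault(disease, set()).add(term)
        if d_freq is not None and d_freq < len(row):
            f = parse_frequency(row[d_freq])
            if f != 1.0:
                frequency[(disease, term)] = f

    if dropped_gene or dropped_dis:
        logger.info("dropped annotation rows with unknown term ids: %d gene, %d disease",
                    dropped_gene, dropped_dis)
    if not gene_to_terms:
        raise AnnotationError(f"{gene_path}: no usable gene annotations")
    if not disease_to_terms:
        raise AnnotationError(f"{disease_path}: no usable disease annotations")

    return AnnotationCorpus(
        gene_to_terms={g: frozenset(ts) for g, ts in gene_to_terms.items()},
        disease_to_terms={d: frozenset(ts) for d, ts in disease_to_terms.items()},
        frequency=frequency,
        dropped_rows={"gene": dropped_gene, "disease": dropped_dis},
    )


# ---------------------------------------------------------------------------
# module-level query helpers (thin wrappers over OntologyGraph methods)
# ---------------------------------------------------------------------------


def ancestors(ontology: OntologyGraph, term_id: str) -> frozenset[str]:
    """Transitive ``is_a`` parents of ``term_id``, excluding itself."""
    return ontology.ancestors(term_id)


def most_depth(ontology: OntologyGraph) -> int:
    """Length in edges of the longest leaf-to-root path in the hierarchy."""
    return ontology.most_depth()
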