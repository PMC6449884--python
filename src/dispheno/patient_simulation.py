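"""Simulated patients and fully synthetic ontology/corpus fixtures.

Three patient grades model decreasing clinical data quality:

* *optimal* — each phenotype annotated to the patient's disease is
  included independently with probability equal to its penetrance
  (frequency); empty draws are redrawn.
* *noisy* — the optimal set plus half as many terms drawn uniformly from
  ontology terms NOT in the disease's propagated annotation set.
* *noisy & imprecision* — half of the optimal terms are first replaced by
  a random proper ancestor (excluding the root), then noise is added, by
  default half the size of the post-replacement set.

The fixture generator builds a random layered DAG with Zipf-vocabulary
text definitions (with tunable parent/child vocabulary overlap), gene and
disease corpora with leaf-biased, optionally module-correlated term sets,
and hpoa-style penetrance values — so the whole similarity stack is
testable without any ontology download.  Fixtures round-trip through the
real OBO/TSV parsers via the writers at the bottom of this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np

from .ontology_core import AnnotationCorpus, OntologyGraph, Term

logger = logging.getLogger("dispheno")

__all__ = [
    "Patient",
    "SimulationError",
    "simulate_optimal",
    "add_noise",
    "add_imprecision",
    "simulate_cohort",
    "make_fixture",
    "toy_fixture",
    "write_obo",
    "write_gene_annotations",
    "write_disease_annotations",
    "write_patients",
    "load_patients",
]


class SimulationError(ValueError):
    """Simulation cannot proceed (empty draws exhausted, no noise pool...)."""


@dataclass(frozen=True)
class Patient:
    """A simulated patient: phenotype term set plus per-term provenance."""

    id: str
    true_target: str
    terms: frozenset[str]
    provenance: dict[str, str] = field(default_factory=dict)  # term -> optimal|noise|imprecise
    seed: int = 0

    def terms_tagged(self, tag: str) -> frozenset[str]:
        return frozenset(t for t, p in self.provenance.items() if p == tag)


def _target_terms(corpus: AnnotationCorpus, target: str) -> frozenset[str]:
    if target in corpus.disease_to_terms:
        return corpus.disease_to_terms[target]
    if target in corpus.gene_to_terms:
        return corpus.gene_to_terms[target]
    raise SimulationError(f"unknown disease/gene id {target!r}")


def simulate_optimal(
    corpus: AnnotationCorpus,
    disease: str,
    n: int,
    seed: int,
    max_retries: int = 100,
) -> list[Patient]:
    """Draw ``n`` optimal patients for one disease.

    Each annotated phenotype is included independently with probability
    equal to its penetrance (a uniform draw not greater than the known
    frequency keeps the phenotype); all-excluded draws are redrawn up to
    ``max_retries`` times.  Deterministic given ``seed``.
    """
    terms = sorted(_target_terms(corpus, disease))
    if not terms:
        raise SimulationError(f"{disease} has no annotated phenotype terms")
    freqs = np.array([corpus.freq(disease, t) for t in terms])
    rng = np.random.default_rng(seed)
    patients = []
    redraws = 0
    for i in range(n):
        for _ in range(max_retries):
            mask = rng.random(len(terms)) <= freqs
            if mask.any():
                break
            redraws += 1
        else:
            raise SimulationError(
                f"{disease}: could not draw a non-empty patient in {max_retries} tries"
            )
        chosen = frozenset(t for t, keep in zip(terms, mask) if keep)
        patients.append(
            Patient(
                id=f"{disease}|optimal|{i}",
                true_target=disease,
                terms=chosen,
                provenance={t: "optimal" for t in chosen},
                seed=seed,
            )
        )
    if redraws:
        logger.info("%s: redrew %d empty optimal patients", disease, redraws)
    return patients


def add_noise(
    patient: Patient,
    ontology: OntologyGraph,
    corpus: AnnotationCorpus,
    seed: int,
    n_noise: int | None = None,
) -> Patient:
    """Contaminate a patient with terms unrelated to its true target.

    Noise candidates are all ontology terms outside the propagated
    annotation set of the true disease/gene; by default half the number of
    the patient's optimal terms are added (rounded up).
    """
    associated = ontology.closure(_target_terms(corpus, patient.true_target))
    pool = sorted(set(ontology.terms) - associated - patient.terms)
    if n_noise is None:
        n_optimal = len(patient.terms_tagged("optimal")) or len(patient.terms)
        n_noise = -(-n_optimal // 2)  # ceil
    if n_noise > len(pool):
        raise SimulationError(
            f"noise pool has {len(pool)} terms, need {n_noise} for {patient.id}"
        )
    rng = np.random.default_rng(seed)
    noise = rng.choice(pool, size=n_noise, replace=False) if n_noise else []
    provenance = dict(patient.provenance)
    provenance.update({t: "noise" for t in noise})
    return replace(
        patient,
        id=patient.id.replace("|optimal|", "|noisy|"),
        terms=patient.terms | frozenset(noise),
        provenance=provenance,
    )


def add_imprecision(
    patient: Patient,
    ontology: OntologyGraph,
    seed: int,
    corpus: AnnotationCorpus | None = None,
    with_noise: bool = True,
    noise_fraction: float = 0.5,
) -> Patient:
    """Blur a patient by generalizing terms, then optionally add noise.

    Half of the optimal terms (rounded down) are each replaced by a
    uniformly drawn proper ancestor, root excluded.  A term whose only
    ancestor is the root is resampled from the remaining optimal terms;
    if none qualifies it is kept and logged.  When ``with_noise`` is set
    (the noisy-&-imprecision recipe), noise terms are then added —
    ``noise_fraction`` of the post-replacement set size, rounded up.
    """
    rng = np.random.default_rng(seed)
    optimal = sorted(patient.terms_tagged("optimal") or patient.terms)
    k = len(optimal) // 2
    order = list(rng.permutation(len(optimal)))
    terms = set(patient.terms)
    provenance = dict(patient.provenance)
    replaced = 0
    while order and replaced < k:
        t = optimal[order.pop(0)]
        candidates = sorted(ontology.ancestors(t) - {ontology.root})
        if not candidates:
            logger.info("%s: %s has no non-root ancestor, kept as-is", patient.id, t)
            continue
        fresh = [c for c in candidates if c not in terms]
        anc = (fresh or candidates)[rng.integers(len(fresh or candidates))]
        terms.discard(t)
        provenance.pop(t, None)
        terms.add(anc)
        provenance[anc] = "imprecise"
        replaced += 1
    blurred = replace(
        patient,
        id=patient.id.replace("|optimal|", "|imprecise|"),
        terms=frozenset(terms),
        provenance=provenance,
    )
    if not with_noise:
        return blurred
    if corpus is None:
        raise ValueError("corpus required when with_noise=True")
    n_noise = int(np.ceil(noise_fraction * len(blurred.terms)))
    noisy = add_noise(blurred, ontology, corpus, seed=int(rng.integers(2**31)), n_noise=n_noise)
    return replace(noisy, id=blurred.id.replace("|imprecise|", "|noisy_imprecise|"))


def simulate_cohort(
    ontology: OntologyGraph,
    corpus: AnnotationCorpus,
    n_per_disease: int,
    seed: int,
    grades: tuple[str, ...] = ("optimal", "noisy", "noisy_imprecise"),
    diseases: list[str] | None = None,
) -> list[Patient]:
    """Simulate patients of the requested grades for every disease.

    With all three grades, each contributes one third of the cohort,
    mirroring the optimal / noisy / noisy-&-imprecision split.
    """
    rng = np.random.default_rng(seed)
    patients: list[Patient] = []
    for disease in sorted(diseases or corpus.disease_to_terms):
        base = simulate_optimal(corpus, disease, n_per_disease, seed=int(rng.integers(2**31)))
        for grade in grades:
            if grade == "optimal":
                patients.extend(base)
            elif grade == "noisy":
                patients.extend(
                    add_noise(p, ontology, corpus, seed=int(rng.integers(2**31)))
                    for p in base
                )
            elif grade == "noisy_imprecise":
                patients.extend(
                    add_imprecision(p, ontology, seed=int(rng.integers(2**31)), corpus=corpus)
                    for p in base
                )
            else:
                raise ValueError(f"unknown patient grade {grade!r}")
    return patients


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

#: Signature whose fixture is pinned to the documented 6-term toy.
_TOY_SIGNATURE = (6, 3, 2, 2)

_TOY_DEFS = {
    "T:0000": ("root term", "phenotypic abnormality"),
    "T:0001": ("limb abnormality", "limb abnormality"),
    "T:0002": ("neural abnormality", "neural abnormality"),
    "T:0003": ("split hand", "split hand"),
    "T:0004": ("absent thumb", "absent thumb"),
    "T:0005": ("neural seizure", "neural seizure"),
}
_TOY_EDGES = [
    ("T:0001", "T:0000"),
    ("T:0002", "T:0000"),
    ("T:0003", "T:0001"),
    ("T:0004", "T:0001"),
    ("T:0005", "T:0002"),
]


def toy_fixture() -> tuple[OntologyGraph, AnnotationCorpus, dict[str, str]]:
    """The documented 6-term toy: two branches under the root, three genes
    annotated to the three leaves, two diseases covering the leaves.

    Hand-checkable facts: most_depth = 2; gene counts give
    IC_gene(T:0001) = ln(3/2), IC_gene(leaf) = ln 3; disease counts give
    IC_disease(T:0005) = ln 2.
    """
    g = nx.DiGraph()
    terms = {}
    for tid, (name, definition) in _TOY_DEFS.items():
        terms[tid] = Term(id=tid, name=name, definition=definition)
        g.add_node(tid)
    g.add_edges_from(_TOY_EDGES)
    onto = OntologyGraph(terms=terms, graph=g, root="T:0000")
    onto.validate()
    corpus = AnnotationCorpus(
        gene_to_terms={
            "g1": frozenset({"T:0003"}),
            "g2": frozenset({"T:0004"}),
            "g3": frozenset({"T:0005"}),
        },
        disease_to_terms={
            "D:0001": frozenset({"T:0003", "T:0004"}),
            "D:0002": frozenset({"T:0005"}),
        },
        frequency={},
    )
    definitions = {tid: d for tid, (_, d) in _TOY_DEFS.items()}
    return onto, corpus, definitions


def make_fixture(
    n_terms: int,
    n_genes: int,
    n_diseases: int,
    depth: int = 4,
    vocab_size: int = 200,
    seed: int = 0,
    mean_terms_per_unit: float = 8.0,
    co_annotation: float = 0.5,
    parent_overlap: float = 0.5,
    extra_parent_prob: float = 0.3,
) -> tuple[OntologyGraph, AnnotationCorpus, dict[str, str]]:
    """Random layered ontology + annotation corpus + definitions.

    * DAG: root at layer 0; every other term gets a layer in 1..depth
      (each layer non-empty), a primary parent in the layer above and,
      with probability ``extra_parent_prob``, an extra parent in any
      shallower layer — acyclic by construction.
    * Definitions: 3-12 tokens over a Zipf-weighted vocabulary;
      ``parent_overlap`` is the expected fraction of tokens copied from
      the primary parent's definition, giving edges textual coherence.
    * Corpus: each gene/disease annotates a leaf-biased random term set
      (mean size ``mean_terms_per_unit``); with probability
      ``co_annotation`` a unit draws most of its terms from one of a few
      shared "modules", creating positive co-annotation (PMI) structure;
      ``co_annotation=0`` gives independent draws.  Disease penetrances
      follow an hpoa-like mix (obligate / very frequent / frequent).

    At the pinned signature (6 terms, 3 genes, 2 diseases, depth 2,
    seed 0) the documented toy fixture is returned verbatim.
    """
    if n_terms < 2:
        raise ValueError("need at least 2 terms")
    if depth < 1 or depth > n_terms - 1:
        raise ValueError(f"depth {depth} infeasible for {n_terms} terms")
    if (n_terms, n_genes, n_diseases, depth) == _TOY_SIGNATURE and seed == 0:
        return toy_fixture()

    rng = np.random.default_rng(seed)

    # --- layered DAG ---
    ids = [f"ST:{i:07d}" for i in range(n_terms)]
    root = ids[0]
    layers: dict[str, int] = {root: 0}
    rest = ids[1:]
    for lv in range(1, depth + 1):  # guarantee every layer is populated
        layers[rest[lv - 1]] = lv
    for tid in rest[depth:]:
        layers[tid] = int(rng.integers(1, depth + 1))
    by_layer: dict[int, list[str]] = {}
    for tid, lv in layers.items():
        by_layer.setdefault(lv, []).append(tid)

    g = nx.DiGraph()
    g.add_nodes_from(ids)
    primary_parent: dict[str, str] = {}
    for tid in ids[1:]:
        lv = layers[tid]
        above = by_layer[lv - 1]
        parent = above[rng.integers(len(above))]
        primary_parent[tid] = parent
        g.add_edge(tid, parent)
        if lv > 1 and rng.random() < extra_parent_prob:
            shallower = [t for l in range(lv) for t in by_layer[l] if t != parent]
            extra = shallower[rng.integers(len(shallower))]
            g.add_edge(tid, extra)

    # --- Zipf-vocabulary definitions with parent overlap ---
    vocab = [f"word{i:04d}" for i in range(vocab_size)]
    zipf_p = 1.0 / np.arange(1, vocab_size + 1)
    zipf_p /= zipf_p.sum()
    tokens: dict[str, list[str]] = {}
    for tid in sorted(ids, key=layers.__getitem__):
        length = int(rng.integers(3, 13))
        toks: list[str] = []
        parent_toks = tokens.get(primary_parent.get(tid, ""), [])
        for _ in range(length):
            if parent_toks and rng.random() < parent_overlap:
                toks.append(parent_toks[rng.integers(len(parent_toks))])
            else:
                toks.append(vocab[rng.choice(vocab_size, p=zipf_p)])
        tokens[tid] = toks

    terms = {
        tid: Term(
            id=tid,
            name=f"synthetic term {i}",
            definition=" ".join(tokens[tid]) + ".",
        )
        for i, tid in enumerate(ids)
    }
    onto = OntologyGraph(terms=terms, graph=g, root=root)
    onto.validate()

    # --- annotation corpora ---
    annotatable = ids[1:]
    layer_arr = np.array([layers[t] for t in annotatable], dtype=float)
    leaf_bias = layer_arr / layer_arr.sum()  # deeper terms drawn more often

    def draw_set() -> frozenset[str]:
        size = max(1, int(rng.poisson(mean_terms_per_unit)))
        size = min(size, len(annotatable))
        idx = rng.choice(len(annotatable), size=size, replace=False, p=leaf_bias)
        return frozenset(annotatable[i] for i in idx)

    # shared "modules" (comorbid phenotype themes); few and heavily reused so
    # the correlation knob produces measurable co-annotation lift
    n_modules = max(2, (n_genes + n_diseases) // 10)
    modules = [draw_set() for _ in range(n_modules)]

    def draw_unit() -> frozenset[str]:
        base = draw_set()
        if co_annotation > 0.0 and rng.random() < co_annotation:
            module = sorted(modules[rng.integers(n_modules)])
            take = max(1, int(round(0.75 * len(module))))
            picked = rng.choice(module, size=take, replace=False)
            base = frozenset(picked) | frozenset(
                sorted(base)[: max(1, len(base) // 2)]
            )
        return base

    gene_to_terms = {f"g{i:03d}": draw_unit() for i in range(n_genes)}
    disease_to_terms = {f"D:{i:04d}": draw_unit() for i in range(n_diseases)}
    frequency: dict[tuple[str, str], float] = {}
    # hpoa-like mix over the frequency-modifier midpoints: obligate terms are
    # the minority; most disease phenotypes are very frequent or frequent
    penetrance_levels = np.array([1.0, 0.895, 0.545, 0.17])
    penetrance_probs = np.array([0.15, 0.35, 0.35, 0.15])
    for disease, ts in disease_to_terms.items():
        for t in sorted(ts):
            f = float(rng.choice(penetrance_levels, p=penetrance_probs))
            if f != 1.0:
                frequency[(disease, t)] = f

    corpus = AnnotationCorpus(
        gene_to_terms=gene_to_terms,
        disease_to_terms=disease_to_terms,
        frequency=frequency,
    )
    definitions = {tid: terms[tid].definition for tid in ids}
    return onto, corpus, definitions


# ---------------------------------------------------------------------------
# Writers (fixtures round-trip through the real parsers)
# ---------------------------------------------------------------------------


def write_obo(ontology: OntologyGraph, path: str | Path) -> None:
    """Write the ontology as a minimal OBO 1.2 flat file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("ontology: dispheno-fixture\n")
        for tid in sorted(ontology.terms):
            term = ontology.terms[tid]
            fh.write("\n[Term]\n")
            fh.write(f"id: {tid}\n")
            fh.write(f"name: {term.name}\n")
            if term.definition:
                fh.write(f'def: "{term.definition}" []\n')
            for syn in term.synonyms:
                fh.write(f'synonym: "{syn}" EXACT []\n')
            for parent in sorted(ontology.graph.successors(tid)):
                fh.write(f"is_a: {parent} ! {ontology.terms[parent].name}\n")


def write_gene_annotations(corpus: AnnotationCorpus, path: str | Path) -> None:
    """genes_to_phenotype.txt dialect: gene symbol + HPO id columns."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ncbi_gene_id\tgene_symbol\thpo_id\thpo_name\n")
        for i, gene in enumerate(sorted(corpus.gene_to_terms)):
            for t in sorted(corpus.gene_to_terms[gene]):
                fh.write(f"{i + 1}\t{gene}\t{t}\t-\n")


def write_disease_annotations(corpus: AnnotationCorpus, path: str | Path) -> None:
    """phenotype.hpoa dialect with a numeric frequency column."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#description: synthetic disease annotations\n")
        fh.write("database_id\tdisease_name\tqualifier\thpo_id\treference\tevidence\tonset\tfrequency\n")
        for disease in sorted(corpus.disease_to_terms):
            for t in sorted(corpus.disease_to_terms[disease]):
                f = corpus.frequency.get((disease, t))
                cell = "" if f is None else repr(f)
                fh.write(f"{disease}\t-\t\t{t}\t-\tTAS\t\t{cell}\n")


def write_patients(patients: list[Patient], path: str | Path) -> None:
    """One row per patient: id, true target, comma-joined term ids; a
    ``<path>.provenance.tsv`` sidecar carries the per-term tags."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient_id\ttrue_target\tterms\n")
        for p in patients:
            fh.write(f"{p.id}\t{p.true_target}\t{','.join(sorted(p.terms))}\n")
    with open(path.with_suffix(path.suffix + ".provenance.tsv"), "w", encoding="utf-8") as fh:
        fh.write("patient_id\tterm_id\tprovenance\n")
        for p in patients:
            for t in sorted(p.terms):
                fh.write(f"{p.id}\t{t}\t{p.provenance.get(t, 'optimal')}\n")


def load_patients(path: str | Path) -> list[Patient]:
    patients = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("patient_id", "#")):
                continue
            pid, target, terms = line.split("\t")
            term_set = frozenset(t for t in terms.split(",") if t)
            patients.append(
                Patient(id=pid, true_target=target, terms=term_set,
                        provenance={t: "optimal" for t in term_set})
            )
    return patients
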