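"""PMI term association and symmetric best-match set similarity.

Two phenotype terms are associated when they appear on the same gene (or
disease) annotation set.  With p(t) the fraction of annotation units
whose propagated term set contains t, and p(a, b) the joint fraction,

    PMI(a, b) = ln( p(a, b) / (p(a) * p(b)) )

Pairs that never co-occur get PMI 0 (no evidence of association) rather
than -inf; in the default *positive* mode negative values are clamped to
0, since a negative association weight would make the best-match max()
prefer weaker matches.  PMI(t, t) = -ln p(t) >= 0.

Set similarity between a patient term set T_p and a candidate term set
T_c is the PMI-weighted best-match average in each direction,

    Sim_set(T_p -> T_c) = (1/N_p) * sum_{t_i in T_p} max_{t_j in T_c} sim(t_i, t_j) * PMI(t_i, t_j)

symmetrized as the mean of the two directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

from .ontology_core import AnnotationCorpus, AnnotationError, OntologyGraph

__all__ = [
    "PmiModel",
    "SetSimilarityResult",
    "build_pmi",
    "directed_set_sim",
    "symmetric_set_sim",
]

SimProvider = Callable[[str, str], float]


@dataclass
class PmiModel:
    """Co-annotation statistics over one annotation source.

    ``term_units`` maps each term to the set of unit indices whose
    propagated annotation set contains it; probabilities and PMI values
    are derived on demand and cached.
    """

    source: str
    unit_count: int
    term_units: dict[str, frozenset[int]]
    mode: str = "positive"  # raw | positive
    _cache: dict[tuple[str, str], float] = field(default_factory=dict, repr=False)

    def term_prob(self, t: str) -> float:
        units = self.term_units.get(t)
        return len(units) / self.unit_count if units else 0.0

    def pair_prob(self, a: str, b: str) -> float:
        ua = self.term_units.get(a)
        ub = self.term_units.get(b)
        if not ua or not ub:
            return 0.0
        return len(ua & ub) / self.unit_count

    def pmi(self, a: str, b: str) -> float:
        """Pointwise mutual information; 0 for never-co-annotated pairs."""
        if a > b:
            a, b = b, a
        key = (a, b)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        p_a = self.term_prob(a)
        if a == b:
            value = -math.log(p_a) if p_a > 0.0 else 0.0
        else:
            p_b = self.term_prob(b)
            p_ab = self.pair_prob(a, b)
            if p_ab == 0.0 or p_a == 0.0 or p_b == 0.0:
                value = 0.0
            else:
                value = math.log(p_ab / (p_a * p_b))
                if self.mode == "positive" and value < 0.0:
                    value = 0.0
        self._cache[key] = value
        return value


@dataclass(frozen=True)
class SetSimilarityResult:
    """Both directed best-match scores and their symmetric mean."""

    sim_p_to_c: float
    sim_c_to_p: float

    @property
    def sim_sym(self) -> float:
        return 0.5 * (self.sim_p_to_c + self.sim_c_to_p)


def build_pmi(
    corpus: AnnotationCorpus,
    ontology: OntologyGraph,
    source: str = "disease",
    mode: str = "positive",
) -> PmiModel:
    """Build a PMI model from the propagated annotation sets of one source.

    ``source`` selects gene units, disease units, or their union; the
    propagation convention matches IC counting (true-path rule).
    """
    if mode not in ("raw", "positive"):
        raise ValueError(f"unknown PMI mode {mode!r}")
    units = corpus.units(source)
    if not units:
        raise AnnotationError(f"annotation corpus empty for source {source!r}")
    term_units: dict[str, set[int]] = {}
    for idx, terms in enumerate(units.values()):
        for t in ontology.closure(terms):
            term_units.setdefault(t, set()).add(idx)
    return PmiModel(
        source=source,
        unit_count=len(units),
        term_units={t: frozenset(u) for t, u in term_units.items()},
        mode=mode,
    )


def directed_set_sim(
    T_from: frozenset[str] | set[str],
    T_to: frozenset[str] | set[str],
    sims: SimProvider,
    pmi: PmiModel | None,
) -> float:
    """Best-match average of PMI-weighted term similarities, T_from -> T_to.

    ``pmi=None`` disables the association weighting (the PMI ablation),
    reducing the score to a plain best-match average.
    """
    if not T_from:
        raise ValueError("T_from is empty")
    if not T_to:
        raise ValueError("T_to is empty")
    total = 0.0
    for t_i in T_from:
        best = -math.inf
        for t_j in T_to:
            s = sims(t_i, t_j)
            if pmi is not None:
                s *= pmi.pmi(t_i, t_j)
            if s > best:
                best = s
        total += best
    return total / len(T_from)


def symmetric_set_sim(
    T_p: frozenset[str] | set[str],
    T_c: frozenset[str] | set[str],
    sims: SimProvider,
    pmi: PmiModel | None,
) -> SetSimilarityResult:
    """Directed scores in both orders plus their mean (order-free score)."""
    return SetSimilarityResult(
        sim_p_to_c=directed_set_sim(T_p, T_c, sims, pmi),
        sim_c_to_p=directed_set_sim(T_c, T_p, sims, pmi),
    )
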