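"""End-to-end similarity pipeline with first-class ablation toggles.

A :class:`DisPheno` object bundles the four ingredients of the measure —
dual-source IC, the definition-weighted DAG, the path-constrained term
similarity, and the PMI association model — behind two calls:
``term_similarity(a, b)`` and ``set_similarity(A, B)``.  Each ingredient
can be switched off independently, mirroring the method's component
ablations:

* ``use_anno``   — dual-source IC vs a single annotation source,
* ``use_depth``  — the (1 - dist/mostDepth) distance factor,
* ``use_weight`` — definition-cosine edge weights vs the plain DAG,
* ``pmi_mode``   — off / raw / positive association weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .definition_weighting import WeightedDag, build_wdag, unit_wdag
from .information_content import ICTable, compute_ic, source_ic
from .ontology_core import AnnotationCorpus, OntologyGraph
from .set_similarity import PmiModel, SetSimilarityResult, build_pmi, symmetric_set_sim
from .term_similarity import term_sim

__all__ = ["PipelineConfig", "DisPheno"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of the measure.

    ``w`` blends gene (w) and disease (1-w) information content.
    ``pmi_source`` chooses which annotation units define co-occurrence;
    rank diseases with the disease corpus, genes with the gene corpus.
    ``anno_source`` is the single IC source used when ``use_anno`` is off.
    """

    w: float = 0.5
    use_anno: bool = True
    use_depth: bool = True
    use_weight: bool = True
    pmi_mode: str = "positive"  # off | raw | positive
    pmi_source: str = "disease"  # gene | disease | union
    anno_source: str = "disease"
    use_stopwords: bool = True
    tie_policy: str = "pessimistic"  # pessimistic | mean

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must lie in [0, 1], got {self.w}")
        if self.pmi_mode not in ("off", "raw", "positive"):
            raise ValueError(f"unknown pmi_mode {self.pmi_mode!r}")
        if self.pmi_source not in ("gene", "disease", "union"):
            raise ValueError(f"unknown pmi_source {self.pmi_source!r}")
        if self.anno_source not in ("gene", "disease"):
            raise ValueError(f"unknown anno_source {self.anno_source!r}")
        if self.tie_policy not in ("pessimistic", "mean"):
            raise ValueError(f"unknown tie_policy {self.tie_policy!r}")


class DisPheno:
    """The assembled similarity measure over one ontology + corpus.

    Prebuilt components may be injected (e.g. to share one WDAG or PMI
    model across a sweep over ``w``); anything not supplied is built from
    the ontology and corpus according to ``config``.
    """

    def __init__(
        self,
        ontology: OntologyGraph,
        corpus: AnnotationCorpus,
        config: PipelineConfig | None = None,
        *,
        ic: ICTable | None = None,
        wdag: WeightedDag | None = None,
        pmi: PmiModel | None = None,
    ) -> None:
        self.ontology = ontology
        self.corpus = corpus
        self.config = config or PipelineConfig()
        cfg = self.config

        if ic is not None:
            self.ic = ic
        elif cfg.use_anno:
            self.ic = compute_ic(ontology, corpus, cfg.w)
        else:
            single = source_ic(ontology, corpus.units(cfg.anno_source))
            one_source = dict(single)
            self.ic = ICTable(ic_gene=one_source, ic_disease=one_source,
                              w=cfg.w, ic=dict(single))

        if wdag is not None:
            self.wdag = wdag
        elif cfg.use_weight:
            self.wdag = build_wdag(ontology, use_stopwords=cfg.use_stopwords)
        else:
            self.wdag = unit_wdag(ontology)

        if pmi is not None:
            self.pmi: PmiModel | None = pmi
        elif cfg.pmi_mode == "off":
            self.pmi = None
        else:
            self.pmi = build_pmi(corpus, ontology, source=cfg.pmi_source,
                                 mode=cfg.pmi_mode)

        self.depth = ontology.most_depth()
        self._sim_cache: dict[tuple[str, str], float] = {}

    def term_similarity(self, t_i: str, t_j: str) -> float:
        """Path-constrained similarity of a term pair (cached)."""
        key = (t_i, t_j) if t_i <= t_j else (t_j, t_i)
        cached = self._sim_cache.get(key)
        if cached is None:
            cached = term_sim(self.ic, self.wdag, self.depth, key[0], key[1],
                              use_depth=self.config.use_depth)
            self._sim_cache[key] = cached
        return cached

    def set_similarity(self, T_p, T_c) -> SetSimilarityResult:
        """Symmetric PMI-weighted best-match similarity of two term sets."""
        return symmetric_set_sim(T_p, T_c, self.term_similarity, self.pmi)
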