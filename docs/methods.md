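# Methods

## The measure

`dispheno` scores the similarity of two phenotype term sets over an
`is_a` ontology DAG in four stages.

**Information content.** Annotations are propagated up the hierarchy
before counting (the true-path rule: annotating a term annotates all its
ancestors), so the root is annotated by every unit and
IC_source(t) = ln(total units / units annotating t or a descendant) is
well defined for every term reached by at least one annotation. Without
propagation most internal terms would have zero explicit annotations and
ln(G/G_t) would be undefined — propagation is the only well-defined
reading. Terms with zero propagated count are pinned at the source's
maximum observed IC: they are treated as maximally specific, which keeps
every downstream product finite (the alternative, +∞, would poison the
best-match maxima). Gene- and disease-derived IC are blended linearly
with a coefficient `w ∈ [0, 1]` (default 0.5, giving both annotation
sources equal weight); `w = 1` is gene-only, `w = 0` disease-only.

**Definition weighting.** Every term definition (falling back to name +
synonyms when empty) is tokenized — lowercased, punctuation stripped,
a small fixed English stop-word list removed — and embedded with plain
two-pass TF-IDF: tf = count/length, idf = ln(N/df), natural log
throughout. No smoothing and no +1 on the idf, so a word present in
every definition carries exactly zero weight and small examples are
hand-checkable. Each `is_a` edge gets the cosine of its endpoints'
vectors, clamped to [0, 1]. An endpoint with an empty vector yields the
neutral weight 1.0: edge weights enter the measure as a product along
paths, and a 0 would annihilate every path through a term merely because
its definition is missing. Only edge weights are materialized, not the
full pairwise cosine matrix — nothing downstream reads non-edge entries.

**Term similarity.** Reachability is the ancestor/descendant relation: a
directed path must connect the two terms, and paths through a common
ancestor do not count. This encodes a structural fact about phenotype
ontologies: low-level sibling terms (e.g. two unrelated limb
malformations) need not share genes or disease symptoms, so they score
exactly 0. For a reachable pair, `dist` is the minimum edge count over
directed paths; among minimum-length paths the maximum weight product is
taken (the least destructive tie-break — the hierarchy may offer several
shortest routes and the measure should not be punished by an arbitrary
one). The shallower term of the pair is the pair's most informative
common ancestor, so min(IC_i, IC_j) is its IC; the form is computed
literally as a min, which stays robust if the two IC sources disagree
about which term is rarer. The distance factor (1 − dist/mostDepth) uses
the hierarchy's longest leaf-to-root path; a single-node hierarchy
(mostDepth 0) uses factor 1.

**Set similarity.** Co-annotation probabilities use the same propagated
unit sets as IC. Pairs that never co-occur get PMI 0 rather than −∞
("no evidence of association" — and the best-match max must stay
defined); PMI(t, t) = −ln p(t) ≥ 0. The default *positive* mode clamps
negative PMI at 0, because a negative association weight would flip the
sign of sim·PMI and make the max prefer *weaker* matches; *raw* mode is
kept for sensitivity analysis. The PMI source defaults to the unit type
being ranked (disease corpus for disease candidates, gene corpus for
gene candidates); `union` pools both. Directed scores are best-match
averages normalized by the originating set's size, symmetrized by the
arithmetic mean of the two directions.

**Ranking.** Candidates are sorted by descending symmetric score. Ties
are charged pessimistically by default (the true target gets the worst
rank of its tie group) — with sparse patients whole candidate lists can
tie at 0, and an optimistic policy would silently report perfect ranks;
a mean-rank policy is available. Gene candidates are ranked through
their annotated phenotype sets directly; mapping causative genes to
diseases is out of scope.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `w` | 0.5 | gene/disease IC blend (nats are source-agnostic) |
| `pmi_mode` | positive | off / raw / positive association weighting |
| `pmi_source` | disease | co-annotation corpus (match the candidate type) |
| `use_anno` | on | dual-source IC; off falls back to `anno_source` |
| `use_depth` | on | (1 − dist/mostDepth) distance factor |
| `use_weight` | on | definition-cosine edge weights vs plain DAG |
| `tie_policy` | pessimistic | rank charged to the true target among ties |

The four toggles mirror the measure's components (`Anno`, `Depth`,
`Weight`, `PMI`) so ablation experiments are one-flag changes. When
`use_anno` is off the single source defaults to the disease corpus,
matching the disease-ranking use case.

## Synthetic fixtures and what they emulate

`make_fixture` generates a miniature of a clinical phenotype corpus:

* a rooted layered DAG (every non-root term has a primary parent one
  layer up and, with probability 0.3, an extra parent in any shallower
  layer — multi-parentage without cycles by construction);
* 3–12-token definitions over a Zipf-weighted vocabulary, with ~50 % of
  tokens copied from the primary parent, so edges carry the textual
  coherence the WDAG is meant to exploit;
* gene and disease annotation sets, leaf-biased (annotations in real
  corpora go to specific terms; ancestors arise by propagation), with a
  co-annotation knob: units draw part of their terms from a small pool of
  shared "modules", emulating comorbid phenotype themes; at knob 0 the
  draws are independent and the co-occurrence covariance of random term
  pairs is centered on zero;
* hpoa-like penetrance values over the frequency-modifier midpoints
  (obligate 1.0 with weight 0.15, very frequent 0.895 / 0.35, frequent
  0.545 / 0.35, occasional 0.17 / 0.15) — most disease phenotypes are
  not obligate, which is what makes even "optimal" patients incomplete.

Patient grades follow the simulation recipes: optimal patients include
each annotated phenotype independently with probability equal to its
penetrance (empty draws are redrawn, 100-attempt budget); noisy patients
add ⌈n_optimal/2⌉ terms drawn uniformly from terms outside the disease's
propagated annotation set; imprecision replaces ⌊n_optimal/2⌋ terms by a
uniformly chosen proper ancestor (root excluded — it carries no
information), then adds noise amounting to half the post-replacement set
size (the noise/imprecision ratio is exposed as `noise_fraction`, since
"half" admits more than one reading). All generators are pure functions
of their inputs and a seed.

What the fixtures do **not** model: real HPO scale (10⁴ terms, 10³–10⁴
diseases), real definition prose, clinical-note extraction artifacts,
and literature-curation biases in annotation frequency. Passing tests on
fixtures therefore demonstrate formula correctness, invariants, and
directional behaviour — not clinical performance.

## The ranking benchmark

`ranking_benchmark(seed)` is the package's end-to-end experiment:
200 terms, depth 6, 40 genes, 30 diseases, ~8 annotations per unit,
co-annotation 0.5; 4 optimal + 4 noisy patients per disease (120 + 120);
all 30 diseases as candidates; three seeds in the acceptance runs. These
sizes keep the whole experiment deterministic and under a few seconds
while leaving room for rank inversions.

Findings the acceptance script reproduces: optimal patients recover the
true disease at rank 1 in ≈ 99 % of cases; the full configuration beats
the Weight-off ablation on noisy mean rank; the PMI-off ablation,
however, is consistently *better* than the full configuration at this
scale (≈ 1.03 vs ≈ 1.08). Per-patient dissection shows why: with only
30 annotation units, a noise term uniquely annotated to one wrong
disease scores sim·PMI = IC·ln 30 on exact match, outweighing the true
disease's more common terms, while PMI's compensating strength —
suppressing the diffuse ancestor-match background — has nothing to
rescue when 30-candidate ranking is already near-saturated without it.
The association weighting is built for dense corpora with large
candidate panels; on small panels the `pmi_mode="off"` ablation can be
the stronger configuration. This is reported as measured, not hidden.

## Numerical choices

* Natural logarithms everywhere (IC, idf, PMI); values are in nats.
* Shortest-path metrics use BFS layering plus a max-product DP
  restricted to nodes on shortest paths; exact, no floating-point path
  search.
* Term-pair similarities are cached per pipeline instance under an
  unordered key (the measure is symmetric by construction).
* Cumulative curves and ranks are exact counts, no interpolation.
* TSV caches print floats with `repr` round-tripping, so cache files are
  byte-stable for a fixed configuration.
* Frequency cells accept HP frequency-modifier ids (mapped to midpoint
  probabilities), `n/m` fractions, percentages, and bare floats; missing
  cells mean 1.0 so unannotated phenotypes stay available to the
  simulator.

## Known limitations

* Only `is_a` edges are used; other OBO relationship types are ignored.
* No OWL parsing, no ontology editing, no cross-ontology mappings.
* No normalized-PMI variant and no k-best-match generalization.
* The gene→disease mapping required to rank diseases for known-gene
  patients is not modeled.
* Ancestor replacement during imprecision simulation can collide with an
  existing patient term; the collision is accepted (set semantics), so
  replaced counts are an upper bound for very small patients.
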