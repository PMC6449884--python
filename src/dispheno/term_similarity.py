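"""Path-constrained term similarity on the weighted DAG.

Two terms are *reachable* when a directed path connects them, i.e. one is
an ancestor of the other (or they are equal); sibling terms with no
ancestor/descendant relation score exactly 0 — in phenotype ontologies,
unlike GO, low-level siblings need not share genes or disease symptoms.
For a reachable pair,

    sim(t_i, t_j) = min(IC(t_i), IC(t_j)) * W(t_i, t_j) * (1 - dist / mostDepth)

where dist is the shortest directed path length between the pair,
mostDepth the longest leaf-to-root path of the hierarchy, and W the
maximum product of edge weights over the minimum-length paths.  The
min-IC factor is the information content of the shallower term (the most
informative common ancestor of the pair on an ancestor chain).
"""

from __future__ import annotations

from .definition_weighting import WeightedDag
from .information_content import ICTable
from .ontology_core import OntologyError, OntologyGraph

__all__ = ["reachable", "path_metrics", "term_sim"]


def reachable(ontology: OntologyGraph, t_i: str, t_j: str) -> bool:
    """True iff a directed path connects the two terms (or they are equal)."""
    ontology._check(t_i)
    ontology._check(t_j)
    return t_i == t_j or t_i in ontology.ancestors(t_j) or t_j in ontology.ancestors(t_i)


def path_metrics(wdag: WeightedDag, t_i: str, t_j: str) -> tuple[int, float]:
    """Shortest directed distance and best weight product between two terms.

    dist is the minimum number of edges over all directed paths between
    the pair; among paths of that length, the maximum product of edge
    weights is returned (the least destructive tie-break).  The identity
    pair has dist 0 and the empty product 1.0.
    """
    onto = wdag.base
    if t_i == t_j:
        onto._check(t_i)
        return 0, 1.0
    if t_j in onto.ancestors(t_i):
        lower, upper = t_i, t_j
    elif t_i in onto.ancestors(t_j):
        lower, upper = t_j, t_i
    else:
        raise OntologyError(f"no directed path between {t_i} and {t_j}")

    g = onto.graph  # edges child -> parent

    # BFS upward from the descendant
    dist_from: dict[str, int] = {lower: 0}
    frontier = [lower]
    while frontier and upper not in dist_from:
        nxt = []
        for node in frontier:
            for parent in g.successors(node):
                if parent not in dist_from:
                    dist_from[parent] = dist_from[node] + 1
                    nxt.append(parent)
        frontier = nxt
    total = dist_from[upper]

    # BFS downward from the ancestor to isolate nodes on shortest paths
    dist_to: dict[str, int] = {upper: 0}
    frontier = [upper]
    while frontier:
        nxt = []
        for node in frontier:
            for child in g.predecessors(node):
                if child not in dist_to:
                    dist_to[child] = dist_to[node] + 1
                    nxt.append(child)
        frontier = nxt

    on_shortest = {
        v for v, d in dist_from.items()
        if v in dist_to and d + dist_to[v] == total
    }
    # layered max-product DP over the shortest-path sub-DAG
    best: dict[str, float] = {lower: 1.0}
    for node in sorted(on_shortest, key=dist_from.__getitem__):
        if node not in best:
            continue
        for parent in g.successors(node):
            if parent in on_shortest and dist_from[parent] == dist_from[node] + 1:
                cand = best[node] * wdag.weight(node, parent)
                if cand > best.get(parent, -1.0):
                    best[parent] = cand
    return total, best[upper]


def term_sim(
    ic: ICTable,
    wdag: WeightedDag,
    depth: int,
    t_i: str,
    t_j: str,
    use_depth: bool = True,
) -> float:
    """Path-constrained similarity of two terms; 0 for unreachable pairs.

    ``depth`` is the hierarchy's mostDepth value.  ``use_depth=False``
    drops the (1 - dist/mostDepth) factor (the Depth ablation).  A
    single-node hierarchy (depth 0) also uses distance factor 1.
    """
    onto = wdag.base
    if not reachable(onto, t_i, t_j):
        return 0.0
    dist, path_weight = path_metrics(wdag, t_i, t_j)
    if use_depth and depth > 0:
        factor = 1.0 - dist / depth
    else:
        factor = 1.0
    return min(ic[t_i], ic[t_j]) * path_weight * factor
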