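"""Independent brute-force oracles for cross-checking the implementation.

Everything here recomputes quantities by exhaustive enumeration or naive
double loops, sharing no code path with the package internals it checks.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------------------
# graph oracles (operate on a plain set of (child, parent) edges)
# ---------------------------------------------------------------------------


def brute_ancestors(edges: set[tuple[str, str]], t: str) -> set[str]:
    """Reflexive-transitive parent closure minus self, by edge chasing."""
    out: set[str] = set()
    frontier = {t}
    while frontier:
        step = {p for (c, p) in edges if c in frontier}
        new = step - out
        out |= new
        frontier = new
    out.discard(t)
    return out


def all_directed_paths(edges: set[tuple[str, str]], src: str, dst: str):
    """Every directed path src -> dst as a list of edges (DFS enumeration)."""
    paths = []

    def walk(node, acc):
        if node == dst:
            paths.append(list(acc))
            return
        for (c, p) in edges:
            if c == node:
                acc.append((c, p))
                walk(p, acc)
                acc.pop()

    walk(src, [])
    return paths


def brute_most_depth(nodes: list[str], edges: set[tuple[str, str]], root: str) -> int:
    """Maximum path length over exhaustive leaf-to-root path enumeration."""
    children = {n: [c for (c, p) in edges if p == n] for n in nodes}
    leaves = [n for n in nodes if not children[n]]
    best = 0
    for leaf in leaves:
        for path in all_directed_paths(edges, leaf, root):
            best = max(best, len(path))
    return best


def brute_path_metrics(
    edges: set[tuple[str, str]],
    weights: dict[tuple[str, str], float],
    a: str,
    b: str,
) -> tuple[int, float]:
    """(min edge count, max weight product among min-length paths) over the
    exhaustive enumeration of all directed paths in either direction."""
    if a == b:
        return 0, 1.0
    paths = all_directed_paths(edges, a, b) + all_directed_paths(edges, b, a)
    assert paths, f"no directed path between {a} and {b}"
    dist = min(len(p) for p in paths)
    best = max(
        math.prod(weights[e] for e in p) for p in paths if len(p) == dist
    )
    return dist, best


# ---------------------------------------------------------------------------
# counting / tf-idf / set-similarity oracles
# ---------------------------------------------------------------------------


def brute_propagated_counts(
    nodes: list[str],
    edges: set[tuple[str, str]],
    unit_to_terms: dict[str, frozenset[str]],
) -> dict[str, int]:
    counts = {n: 0 for n in nodes}
    for terms in unit_to_terms.values():
        closure: set[str] = set()
        for t in terms:
            closure.add(t)
            closure |= brute_ancestors(edges, t)
        for t in closure:
            counts[t] += 1
    return counts


def brute_tfidf(docs: dict[str, list[str]]) -> dict[str, dict[str, float]]:
    """Two-pass tf/df recomputation: tf = n/len, idf = ln(N/df)."""
    n = len(docs)
    df: dict[str, int] = {}
    for toks in docs.values():
        for w in set(toks):
            df[w] = df.get(w, 0) + 1
    out = {}
    for tid, toks in docs.items():
        vec = {}
        for w in set(toks):
            weight = (toks.count(w) / len(toks)) * math.log(n / df[w])
            if weight != 0.0:
                vec[w] = weight
        out[tid] = vec
    return out


def brute_directed_set_sim(T_from, T_to, sim, pmi_weight) -> float:
    """Naive double loop over both sets; pmi_weight(a, b) may return 1."""
    acc = 0.0
    for t_i in sorted(T_from):
        acc += max(sim(t_i, t_j) * pmi_weight(t_i, t_j) for t_j in sorted(T_to))
    return acc / len(T_from)


# ---------------------------------------------------------------------------
# random test-case generators
# ---------------------------------------------------------------------------


def random_dag(rng: np.random.Generator, n_max: int = 12):
    """A random rooted DAG: node list, edge set, root ('N0').

    Nodes are created in topological order; every non-root node gets 1-2
    parents among earlier nodes, so the root is the unique apex.
    """
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"N{i}" for i in range(n)]
    edges: set[tuple[str, str]] = set()
    for i in range(1, n):
        n_parents = 1 + int(rng.random() < 0.4)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            edges.add((nodes[i], nodes[int(p)]))
    return nodes, edges, nodes[0]


def random_corpus(rng: np.random.Generator, nodes: list[str], n_units: int = 6):
    return {
        f"u{i}": frozenset(
            rng.choice(nodes, size=int(rng.integers(1, min(4, len(nodes)) + 1)),
                       replace=False)
        )
        for i in range(n_units)
    }
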