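"""Brute-force reference implementations used only as test oracles.

Each function recomputes a quantity by direct enumeration or closed form,
independently of the package's implementation path.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import networkx as nx


def brute_path_centralities(graph: nx.Graph) -> dict[str, dict]:
    """Betweenness, stress and closeness by explicit all-shortest-paths
    enumeration over every unordered node pair."""
    nodes = list(graph.nodes)
    betweenness = {v: 0.0 for v in nodes}
    stress = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if not nx.has_path(graph, s, t):
            continue
        paths = list(nx.all_shortest_paths(graph, s, t))
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p[1:-1])
            if through:
                stress[v] += through
                betweenness[v] += through / len(paths)
    closeness = {}
    for v in nodes:
        dists = nx.single_source_shortest_path_length(graph, v)
        reach = {w: d for w, d in dists.items() if w != v}
        closeness[v] = (len(reach) / sum(reach.values())) if reach else 0.0
    return {"betweenness": betweenness, "stress": stress, "closeness": closeness}


def brute_bh(pvalues: list[float]) -> list[float]:
    """Step-up BH adjustment straight from its definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, m * pvalues[i] / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def hypergeom_upper_tail(N: int, K: int, n: int, a: int) -> Fraction:
    """Exact P(X >= a) for X ~ Hypergeometric(N, K, n), as a Fraction."""
    total = comb(N, n)
    acc = Fraction(0)
    for x in range(a, min(K, n) + 1):
        if n - x > N - K:
            continue
        acc += Fraction(comb(K, x) * comb(N - K, n - x), total)
    return acc


def brute_ffl_scan(edges) -> set[tuple[str, str, str]]:
    """All (mirna, tf, gene) triples by scanning the full cross product.

    ``edges`` is an iterable of (source, target, edge_type) tuples.
    """
    mt, mg, tg = set(), set(), set()
    for s, t, et in edges:
        {"mirna_tf": mt, "mirna_gene": mg, "tf_gene": tg}[et].add((s, t))
    mirnas = {s for s, _ in mt} | {s for s, _ in mg}
    tfs = {t for _, t in mt} | {s for s, _ in tg}
    genes = {t for _, t in mg} | {t for _, t in tg}
    found = set()
    for m in mirnas:
        for t in tfs:
            for g in genes:
                if (m, t) in mt and (m, g) in mg and (t, g) in tg:
                    found.add((m, t, g))
    return found
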