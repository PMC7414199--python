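"""PPI network construction, five-centrality ranking and hub-gene calling.

Edges from BioGRID-style tables (kept when they carry at least one
experimental evidence) and HIPPIE-style tables (kept when the confidence
score lies in [0.63, 1]) are merged into one undirected simple graph
around a set of seed genes.  Every node is scored under five centralities
— degree, betweenness, closeness, stress and the edge-percolated
component (EPC) — and hub genes are the seeds appearing in the top-n of
all five.

Definitions used (n_c = size of v's connected component C(v), sigma_st =
number of shortest s-t paths, sigma_st(v) those passing through v):

    degree(v)       incident edge count
    betweenness(v)  sum over unordered pairs s<t (both != v) of
                    sigma_st(v)/sigma_st, unnormalized
    stress(v)       sum over the same pairs of sigma_st(v)
    closeness(v)    (n_c - 1) / sum of d(v, w) over w in C(v); 0 if isolated
    epc(v)          mean over Monte-Carlo percolation realizations (each
                    edge kept independently with probability p) of the
                    number of nodes still connected to v
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .config import PipelineConfig

logger = logging.getLogger(__name__)

CENTRALITY_MEASURES = ("degree", "betweenness", "closeness", "stress", "epc")

_BIOGRID_COLS = {"partner_a", "partner_b", "evidence_count"}
_HIPPIE_COLS = {"partner_a", "partner_b", "score"}


def _check_columns(table: pd.DataFrame, required: set[str], label: str) -> None:
    missing = required - set(table.columns)
    if missing:
        raise ValueError(
            f"{label} PPI table is missing columns {sorted(missing)}; "
            f"found {list(table.columns)}")


def build_ppi(
    seed_genes,
    biogrid_table: pd.DataFrame | None,
    hippie_table: pd.DataFrame | None,
    config: PipelineConfig,
    regulation: dict[str, str] | None = None,
) -> nx.Graph:
    """Evidence-filtered undirected PPI graph around ``seed_genes``.

    BioGRID-like rows need ``evidence_count >= 1``; HIPPIE-like rows need
    ``hippie_min_score <= score <= 1``.  Only edges incident to at least
    one seed survive; self-loops are dropped, parallel edges merged with
    provenance concatenated.  Isolated seeds are kept as nodes.
    """
    seeds = set(seed_genes)
    if not seeds:
        raise ValueError("seed gene set is empty")
    regulation = regulation or {}

    graph = nx.Graph()
    for gene in sorted(seeds):
        graph.add_node(gene, role="seed",
                       regulation=regulation.get(gene, "none"))

    def add_edge(u: str, v: str, prov: str) -> None:
        if u == v:
            return
        if u not in seeds and v not in seeds:
            return
        for node in (u, v):
            if node not in graph:
                graph.add_node(node, role="interactor",
                               regulation=regulation.get(node, "none"))
        if graph.has_edge(u, v):
            graph[u][v]["provenance"].append(prov)
        else:
            graph.add_edge(u, v, provenance=[prov])

    if biogrid_table is not None and len(biogrid_table):
        _check_columns(biogrid_table, _BIOGRID_COLS, "BioGRID-like")
        kept = biogrid_table[biogrid_table["evidence_count"] >= 1]
        for row in kept.itertuples(index=False):
            add_edge(str(row.partner_a), str(row.partner_b),
                     f"biogrid:evidence={int(row.evidence_count)}")
    if hippie_table is not None and len(hippie_table):
        _check_columns(hippie_table, _HIPPIE_COLS, "HIPPIE-like")
        lo = config.hippie_min_score
        kept = hippie_table[
            (hippie_table["score"] >= lo) & (hippie_table["score"] <= 1.0)]
        for row in kept.itertuples(index=False):
            add_edge(str(row.partner_a), str(row.partner_b),
                     f"hippie:score={row.score:g}")

    logger.info(
        "build_ppi: %d nodes (%d seeds), %d edges after filtering",
        graph.number_of_nodes(), len(seeds), graph.number_of_edges())
    return graph


# ---------------------------------------------------------------------------
# centralities


def _bfs_sigma(adj: list[list[int]], source: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted single-source distances and shortest-path counts."""
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    dist[source] = 0.0
    sigma[source] = 1.0
    frontier = [source]
    d = 0
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if np.isinf(dist[w]):
                    dist[w] = d + 1
                    nxt.append(w)
                if dist[w] == d + 1:
                    sigma[w] += sigma[u]
        frontier = nxt
        d += 1
    return dist, sigma


def stress_centrality(graph: nx.Graph) -> dict:
    """Number of shortest paths through each node (endpoints excluded).

    Counts each unordered (s, t) pair once: stress(v) =
    sum_{s<t, s!=v!=t} sigma_st(v).
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    adj: list[list[int]] = [[] for _ in range(n)]
    for u, v in graph.edges:
        adj[idx[u]].append(idx[v])
        adj[idx[v]].append(idx[u])

    dist = np.empty((n, n))
    sigma = np.empty((n, n))
    for i in range(n):
        dist[i], sigma[i] = _bfs_sigma(adj, i, n)

    stress = np.zeros(n)
    for v in range(n):
        # sigma_st(v) = sigma_sv * sigma_vt when d(s,v) + d(v,t) = d(s,t)
        through = dist[:, v][:, None] + dist[v, :][None, :]
        on_path = np.isfinite(dist) & (through == dist)
        contrib = np.outer(sigma[:, v], sigma[v, :]) * on_path
        contrib[v, :] = 0.0
        contrib[:, v] = 0.0
        np.fill_diagonal(contrib, 0.0)
        stress[v] = contrib.sum() / 2.0
    return {nodes[i]: float(stress[i]) for i in range(n)}


def epc_centrality(
    graph: nx.Graph,
    reps: int,
    retain_p: float,
    rng: np.random.Generator,
) -> dict:
    """Edge-percolated-component centrality by Monte Carlo.

    In each realization every edge is kept independently with probability
    ``retain_p``; a node's score for that realization is the number of
    other nodes in its surviving component, and epc(v) is the mean over
    realizations.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    edges = np.array([(idx[u], idx[v]) for u, v in graph.edges], dtype=np.int64)
    total = np.zeros(n)
    m = len(edges)
    for _ in range(reps):
        if m:
            mask = rng.random(m) < retain_p
            kept = edges[mask]
        else:
            kept = np.empty((0, 2), dtype=np.int64)
        mat = coo_matrix(
            (np.ones(len(kept)), (kept[:, 0], kept[:, 1])), shape=(n, n))
        _, labels = connected_components(mat, directed=False)
        sizes = np.bincount(labels, minlength=labels.max() + 1 if n else 0)
        total += sizes[labels] - 1
    epc = total / reps
    return {nodes[i]: float(epc[i]) for i in range(n)}


def compute_centralities(
    graph: nx.Graph,
    config: PipelineConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """All five centralities plus a dense rank per measure (1 = highest)."""
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot compute centralities on an empty network")
    degree = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    closeness = nx.closeness_centrality(graph, wf_improved=False)
    stress = stress_centrality(graph)
    epc = epc_centrality(graph, config.epc_reps, config.epc_retain_p, rng)

    table = pd.DataFrame({
        "degree": pd.Series(degree, dtype=float),
        "betweenness": pd.Series(betweenness, dtype=float),
        "closeness": pd.Series(closeness, dtype=float),
        "stress": pd.Series(stress, dtype=float),
        "epc": pd.Series(epc, dtype=float),
    }).sort_index()
    table.index.name = "node"
    for measure in CENTRALITY_MEASURES:
        table[f"rank_{measure}"] = (
            table[measure].rank(method="dense", ascending=False).astype(int))
    return table


def identify_hubs(
    centrality_table: pd.DataFrame,
    n: int,
    seed_genes=None,
    restrict_to_seeds: bool = True,
) -> set[str]:
    """Seeds in the top-n of all five centrality measures.

    Top-n uses dense ranks, so every node tied at the cutoff value is
    included.  The intersection over the five per-measure top sets is then
    restricted to ``seed_genes`` when ``restrict_to_seeds`` is set.
    """
    if n < 1:
        raise ValueError(f"top-n cutoff must be >= 1, got {n}")
    n_nodes = len(centrality_table)
    if n > n_nodes:
        logger.warning("identify_hubs: n=%d exceeds node count %d; clamped",
                       n, n_nodes)
        n = n_nodes
    hubs: set[str] | None = None
    for measure in CENTRALITY_MEASURES:
        top = set(centrality_table.index[centrality_table[f"rank_{measure}"] <= n])
        hubs = top if hubs is None else hubs & top
    assert hubs is not None
    if restrict_to_seeds:
        if seed_genes is None:
            raise ValueError("restrict_to_seeds=True requires seed_genes")
        hubs &= set(seed_genes)
    return hubs
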