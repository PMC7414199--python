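"""miRNA -> TF -> gene feed-forward-loop mining.

Typed regulatory edges (miRNA->gene, miRNA->TF, TF->gene) from several
source dialects are filtered with source-specific thresholds, pruned to
miRNAs conserved between human and mouse, and scanned for 3-node
feed-forward loops: triples (m, T, g) where the miRNA represses both the
TF and the gene while the TF regulates the same gene.  The union of all
motif edges forms the merged FFL network, whose topology (degree
distribution, clustering and topological coefficients, betweenness,
closeness, shortest-path-length histogram, log-log power-law fit) is
summarized on its undirected projection.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .config import PipelineConfig

logger = logging.getLogger(__name__)

EDGE_TYPES = ("mirna_gene", "mirna_tf", "tf_gene")
MIRNA_EDGE_TYPES = ("mirna_gene", "mirna_tf")

#: columns each source dialect must provide beyond source/target/edge_type/species
DIALECT_COLUMNS = {
    "mirwalk": ("score", "region", "binding_gap"),
    "mirsearch": ("confidence_flag",),
    "starbase": ("score",),
    "chipbase": ("upstream_bp",),
    "itfp": (),
    "enrichr_tf": ("evidence_p",),
}
MIRNA_DIALECTS = ("mirwalk", "mirsearch", "starbase")
TF_DIALECTS = ("chipbase", "itfp", "enrichr_tf")

_EDGE_KEY = ["source", "target", "edge_type", "species"]

_SPECIES_PREFIX = re.compile(r"^(hsa|mmu)-", re.IGNORECASE)
_ARM_SUFFIX = re.compile(r"-(5p|3p)$", re.IGNORECASE)


def normalize_mirna(name: str, keep_arm: bool = True) -> str:
    """Species-agnostic, case-insensitive miRNA base name.

    Strips the ``hsa-``/``mmu-`` species prefix and lowercases; the
    ``-5p``/``-3p`` arm suffix is kept by default (the stricter identity)
    and dropped with ``keep_arm=False``.
    """
    base = _SPECIES_PREFIX.sub("", name).lower()
    if not keep_arm:
        base = _ARM_SUFFIX.sub("", base)
    return base


def _keep_row(row, config: PipelineConfig) -> bool:
    dialect = row.dialect
    if dialect == "mirwalk":
        return (row.score >= config.mirna_score_min
                and row.region == "3UTR" and int(row.binding_gap) == 1)
    if dialect == "starbase":
        return row.score >= config.mirna_score_min
    if dialect == "mirsearch":
        return str(row.confidence_flag).lower() == "high"
    if dialect == "chipbase":
        return row.upstream_bp <= config.upstream_window_bp
    if dialect == "enrichr_tf":
        return row.evidence_p < config.tf_p_max
    if dialect == "itfp":
        return True
    raise ValueError(f"unknown regulatory-edge dialect {dialect!r}")


def filter_edges(raw_edges: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Apply source-specific thresholds and de-duplicate.

    ``raw_edges`` needs columns ``source``, ``target``, ``edge_type``,
    ``species``, ``dialect`` plus the score columns its dialects require
    (miRWalk-like: score >= threshold AND 3UTR region AND binding gap 1;
    miRSearch-like: categorical high-confidence flag; Starbase-like:
    score >= threshold; ChIPBase-like: binding site within the upstream
    window; Enrichr-TF-like: evidence p below threshold; ITFP-like: kept
    as published).  Edges equal on (source, target, edge_type, species)
    are merged, provenance dialects joined with ``;``.
    """
    required = set(_EDGE_KEY + ["dialect"])
    missing = required - set(raw_edges.columns)
    if missing:
        raise ValueError(f"regulatory edge table lacks columns {sorted(missing)}")
    bad_type = set(raw_edges["edge_type"]) - set(EDGE_TYPES)
    if bad_type:
        raise ValueError(f"unknown edge types {sorted(bad_type)}")

    for i, row in enumerate(raw_edges.itertuples(index=False)):
        dialect = row.dialect
        if dialect not in DIALECT_COLUMNS:
            raise ValueError(f"row {i}: unknown dialect {dialect!r}")
        for col in DIALECT_COLUMNS[dialect]:
            if col not in raw_edges.columns or pd.isna(getattr(row, col)):
                raise ValueError(
                    f"row {i}: dialect {dialect!r} requires column {col!r}")
        if row.source == row.target:
            raise ValueError(f"row {i}: self-edge {row.source!r}")

    keep_mask = [
        _keep_row(row, config) for row in raw_edges.itertuples(index=False)]
    kept = raw_edges[np.asarray(keep_mask, dtype=bool)].copy()
    if kept.empty:
        return pd.DataFrame(columns=_EDGE_KEY + ["provenance"])
    merged = (
        kept.groupby(_EDGE_KEY, sort=True)["dialect"]
        .apply(lambda s: ";".join(sorted(set(s))))
        .rename("provenance")
        .reset_index()
    )
    logger.info("filter_edges: kept %d of %d rows -> %d unique edges",
                len(kept), len(raw_edges), len(merged))
    return merged


def conservation_filter(
    human_edges: pd.DataFrame,
    mouse_edges: pd.DataFrame,
    keep_arm: bool = True,
) -> tuple[set[str], pd.DataFrame]:
    """Keep only miRNAs whose base name occurs in both species.

    ``final_mirnas`` holds the surviving *human* identifiers.  All
    miRNA->gene and miRNA->TF edges from non-conserved miRNAs are removed;
    TF->gene edges are left untouched.  Idempotent.
    """
    def mirna_bases(edges: pd.DataFrame) -> set[str]:
        if edges.empty:
            return set()
        mask = edges["edge_type"].isin(MIRNA_EDGE_TYPES)
        return {normalize_mirna(s, keep_arm) for s in edges.loc[mask, "source"]}

    conserved = mirna_bases(human_edges) & mirna_bases(mouse_edges)
    if human_edges.empty:
        return set(), human_edges.copy()
    is_mirna_edge = human_edges["edge_type"].isin(MIRNA_EDGE_TYPES)
    src_ok = human_edges["source"].map(
        lambda s: normalize_mirna(s, keep_arm) in conserved)
    pruned = human_edges[~is_mirna_edge | src_ok].reset_index(drop=True)
    final_mirnas = set(pruned.loc[pruned["edge_type"].isin(MIRNA_EDGE_TYPES),
                                  "source"])
    logger.info("conservation_filter: %d conserved miRNAs, %d of %d edges kept",
                len(final_mirnas), len(pruned), len(human_edges))
    return final_mirnas, pruned


def enumerate_ffls(edges: pd.DataFrame) -> pd.DataFrame:
    """All 3-node feed-forward loops in a typed edge set.

    A loop is a triple (mirna, tf, gene) whose three edges
    mirna->tf (mirna_tf), mirna->gene (mirna_gene) and tf->gene (tf_gene)
    are all present.  Output is sorted lexicographically and invariant to
    edge order and duplicates.
    """
    if edges.empty:
        return pd.DataFrame(columns=["mirna", "tf", "gene"])
    by_type = {
        t: set(map(tuple, edges.loc[edges["edge_type"] == t,
                                    ["source", "target"]].to_numpy()))
        for t in EDGE_TYPES
    }
    mirna_targets: dict[str, set[str]] = {}
    for m, g in by_type["mirna_gene"]:
        mirna_targets.setdefault(m, set()).add(g)
    tf_targets: dict[str, set[str]] = {}
    for t, g in by_type["tf_gene"]:
        tf_targets.setdefault(t, set()).add(g)

    rows = []
    for m, t in by_type["mirna_tf"]:
        shared = mirna_targets.get(m, set()) & tf_targets.get(t, set())
        rows.extend({"mirna": m, "tf": t, "gene": g} for g in shared)
    result = pd.DataFrame(rows, columns=["mirna", "tf", "gene"])
    return result.sort_values(["mirna", "tf", "gene"]).reset_index(drop=True)


@dataclass
class FFLNetwork:
    """Merged network of all edges participating in >= 1 feed-forward loop."""

    motifs: pd.DataFrame
    mirnas: tuple[str, ...] = field(default_factory=tuple)
    tfs: tuple[str, ...] = field(default_factory=tuple)
    genes: tuple[str, ...] = field(default_factory=tuple)
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_nodes(self) -> int:
        return len(self.mirnas) + len(self.tfs) + len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_type_counts(self) -> dict[str, int]:
        counts = self.edges["edge_type"].value_counts().to_dict() if len(self.edges) else {}
        return {t: int(counts.get(t, 0)) for t in EDGE_TYPES}

    def summary_table(self) -> pd.DataFrame:
        """Per-relationship edge and node participation counts."""
        counts = self.edge_type_counts()

        def participants(edge_type: str, role: str) -> int:
            sub = self.edges[self.edges["edge_type"] == edge_type]
            col = "source" if role == "source" else "target"
            return int(sub[col].nunique())

        rows = [
            {"relationship": "miRNA-gene",
             "n_edges": counts["mirna_gene"],
             "n_mirnas": participants("mirna_gene", "source"),
             "n_tfs": 0,
             "n_genes": participants("mirna_gene", "target")},
            {"relationship": "TF-gene",
             "n_edges": counts["tf_gene"],
             "n_mirnas": 0,
             "n_tfs": participants("tf_gene", "source"),
             "n_genes": participants("tf_gene", "target")},
            {"relationship": "miRNA-TF",
             "n_edges": counts["mirna_tf"],
             "n_mirnas": participants("mirna_tf", "source"),
             "n_tfs": participants("mirna_tf", "target"),
             "n_genes": 0},
        ]
        return pd.DataFrame(rows)

    def undirected_projection(self) -> nx.Graph:
        graph = nx.Graph()
        graph.add_nodes_from(self.mirnas, node_class="mirna")
        graph.add_nodes_from(self.tfs, node_class="tf")
        graph.add_nodes_from(self.genes, node_class="gene")
        for row in self.edges.itertuples(index=False):
            graph.add_edge(row.source, row.target)
        return graph


def build_ffl_network(
    ffl_list: pd.DataFrame,
    all_edges: pd.DataFrame | None = None,
    include_non_motif_edges: bool = False,
) -> FFLNetwork:
    """Merge motif instances into one network.

    By default the merged edge set is exactly the union of the three edges
    of every motif.  With ``include_non_motif_edges=True`` (requires
    ``all_edges``) every filtered edge is included instead.
    """
    if include_non_motif_edges:
        if all_edges is None:
            raise ValueError("include_non_motif_edges requires all_edges")
        edges = all_edges[["source", "target", "edge_type"]].drop_duplicates()
    else:
        rows = []
        for row in ffl_list.itertuples(index=False):
            rows.append((row.mirna, row.tf, "mirna_tf"))
            rows.append((row.mirna, row.gene, "mirna_gene"))
            rows.append((row.tf, row.gene, "tf_gene"))
        edges = pd.DataFrame(rows, columns=["source", "target", "edge_type"]
                             ).drop_duplicates()
    edges = edges.sort_values(["edge_type", "source", "target"]).reset_index(drop=True)

    mirnas = set(edges.loc[edges["edge_type"].isin(MIRNA_EDGE_TYPES), "source"])
    tfs = (set(edges.loc[edges["edge_type"] == "mirna_tf", "target"])
           | set(edges.loc[edges["edge_type"] == "tf_gene", "source"]))
    genes = (set(edges.loc[edges["edge_type"] == "mirna_gene", "target"])
             | set(edges.loc[edges["edge_type"] == "tf_gene", "target"]))
    return FFLNetwork(
        motifs=ffl_list.reset_index(drop=True),
        mirnas=tuple(sorted(mirnas)),
        tfs=tuple(sorted(tfs)),
        genes=tuple(sorted(genes)),
        edges=edges,
    )


# ---------------------------------------------------------------------------
# topology statistics


def _topological_coefficient(graph: nx.Graph, v) -> float:
    k = graph.degree(v)
    if k < 2:
        return 0.0
    neighbors = set(graph[v])
    shared_counts = []
    for u in graph.nodes:
        if u == v:
            continue
        common = len(neighbors & set(graph[u]))
        if common == 0:
            continue
        j = common + (1 if graph.has_edge(u, v) else 0)
        shared_counts.append(j)
    if not shared_counts:
        return 0.0
    return float(np.mean(shared_counts) / k)


def fit_power_law(counts: dict[int, int]) -> dict:
    """Least-squares line through (log10 k, log10 count) over nonzero bins.

    Returns slope, intercept and R^2; with a single bin the fit is
    degenerate (slope 0, R^2 1 by convention).
    """
    ks = np.array([k for k, c in sorted(counts.items()) if k > 0 and c > 0],
                  dtype=float)
    cs = np.array([counts[int(k)] for k in ks], dtype=float)
    if ks.size == 0:
        return {"slope": np.nan, "intercept": np.nan, "r_squared": np.nan}
    x, y = np.log10(ks), np.log10(cs)
    if ks.size == 1:
        return {"slope": 0.0, "intercept": float(y[0]), "r_squared": 1.0}
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r_sq = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return {"slope": float(slope), "intercept": float(intercept),
            "r_squared": r_sq}


def topology_stats(network: FFLNetwork, config: PipelineConfig | None = None) -> dict:
    """Topology summary of the merged network's undirected projection.

    Returns a dict with per-node tables and distributions:

    - ``node_table``: degree, clustering coefficient, topological
      coefficient, betweenness (unnormalized), closeness per node
    - ``degree_histogram``: degree -> node count
    - ``clustering_by_degree`` / ``topological_by_degree``: mean
      coefficient per degree class
    - ``path_length_histogram``: distance -> connected-pair count
    - ``power_law_fit``: log-log least-squares fit of the degree histogram
    """
    graph = network.undirected_projection()
    if graph.number_of_nodes() == 0:
        raise ValueError("topology_stats needs a non-empty network")

    degree = dict(graph.degree())
    clustering = nx.clustering(graph)
    topo = {v: _topological_coefficient(graph, v) for v in graph.nodes}
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    closeness = nx.closeness_centrality(graph, wf_improved=False)

    node_table = pd.DataFrame({
        "degree": pd.Series(degree, dtype=float),
        "clustering": pd.Series(clustering, dtype=float),
        "topological_coefficient": pd.Series(topo, dtype=float),
        "betweenness": pd.Series(betweenness, dtype=float),
        "closeness": pd.Series(closeness, dtype=float),
    }).sort_index()
    node_table.index.name = "node"

    degree_hist: dict[int, int] = {}
    for v, k in degree.items():
        degree_hist[k] = degree_hist.get(k, 0) + 1

    def by_degree(values: dict) -> dict[int, float]:
        acc: dict[int, list[float]] = {}
        for v, k in degree.items():
            acc.setdefault(k, []).append(values[v])
        return {k: float(np.mean(vals)) for k, vals in sorted(acc.items())}

    path_hist: dict[int, int] = {}
    for u, dists in nx.all_pairs_shortest_path_length(graph):
        for w, d in dists.items():
            if d > 0:
                path_hist[d] = path_hist.get(d, 0) + 1
    path_hist = {d: c // 2 for d, c in sorted(path_hist.items())}

    return {
        "node_table": node_table,
        "degree_histogram": dict(sorted(degree_hist.items())),
        "clustering_by_degree": by_degree(clustering),
        "topological_by_degree": by_degree(topo),
        "path_length_histogram": path_hist,
        "power_law_fit": fit_power_law(degree_hist),
    }
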