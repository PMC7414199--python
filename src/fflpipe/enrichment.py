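"""Gene-set over-representation analysis.

One-sided Fisher exact tests of a query gene list against each set of a
GMT-style library, BH-adjusted within the library (never pooled across
libraries), plus the union of query genes that fall in any significantly
enriched set — the seed list for the downstream PPI stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .meta_deg import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetLibrary:
    """A named collection of gene sets (the in-memory form of a GMT file)."""

    library_name: str
    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(genes)

    def __len__(self) -> int:
        return len(self.sets)


def fisher_enrich(
    query_genes,
    library: GeneSetLibrary,
    universe,
    enrich_alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of ``query_genes`` in each set of ``library``.

    Each set is first intersected with the universe; sets disjoint from it
    are skipped with a warning.  For each remaining set the 2x2 table is

        a = |query & set|      b = |query \\ set|
        c = |set \\ query|     d = |universe| - a - b - c

    and p is the one-sided (over-representation) Fisher exact probability,
    identical to the hypergeometric upper tail P(X >= a).  BH adjustment is
    applied across the tested sets of this library only; ``significant``
    flags bh_p < enrich_alpha.

    Results come back sorted by (p, set_name) and are therefore invariant
    to the order of sets in the source file.
    """
    universe = set(universe)
    query = set(query_genes)
    if not universe:
        raise ValueError("universe is empty")
    if not query:
        raise ValueError("query gene list is empty")
    stray = query - universe
    if stray:
        raise ValueError(
            f"query genes outside the universe: {sorted(stray)[:5]}"
            f"{'...' if len(stray) > 5 else ''}")

    rows = []
    for set_name in sorted(library.sets):
        members = library.sets[set_name] & universe
        if not members:
            logger.warning(
                "fisher_enrich[%s]: set %r disjoint from universe, skipped",
                library.library_name, set_name)
            continue
        overlap = sorted(query & members)
        a = len(overlap)
        b = len(query) - a
        c = len(members) - a
        d = len(universe) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({
            "set_name": set_name,
            "overlap_genes": ";".join(overlap),
            "a": a, "b": b, "c": c, "d": d,
            "p": float(p),
        })
    result = pd.DataFrame(
        rows, columns=["set_name", "overlap_genes", "a", "b", "c", "d", "p"])
    if not result.empty:
        result["bh_p"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = result["bh_p"] < enrich_alpha
        result = result.sort_values(["p", "set_name"]).reset_index(drop=True)
    else:
        result["bh_p"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    result.insert(0, "library", library.library_name)
    return result


def enriched_union(
    results_by_library: list[pd.DataFrame],
    query_genes,
) -> set[str]:
    """Union of query genes appearing in any significantly enriched set."""
    if not results_by_library:
        raise ValueError("need enrichment results for at least one library")
    query = set(query_genes)
    union: set[str] = set()
    for result in results_by_library:
        if result.empty:
            continue
        for _, row in result[result["significant"]].iterrows():
            genes = set(row["overlap_genes"].split(";")) if row["overlap_genes"] else set()
            union |= genes & query
    return union


def membership_table(
    results_by_library: list[pd.DataFrame],
) -> pd.DataFrame:
    """Long-form gene <-> significant-set membership (circos-plot content)."""
    rows = []
    for result in results_by_library:
        if result.empty:
            continue
        for _, row in result[result["significant"]].iterrows():
            for gene in (row["overlap_genes"].split(";") if row["overlap_genes"] else []):
                rows.append({
                    "library": row["library"],
                    "set_name": row["set_name"],
                    "gene": gene,
                })
    return pd.DataFrame(rows, columns=["library", "set_name", "gene"]).sort_values(
        ["library", "set_name", "gene"]).reset_index(drop=True)
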