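"""Synthetic inputs with the statistical structure the pipeline assumes.

Every file the pipeline consumes can be generated here: two expression
studies sharing planted differentially expressed genes, GMT gene-set
libraries enriched for the planted genes, BioGRID/HIPPIE-style PPI edge
tables around designated seed genes, and matched human/mouse regulatory
edge tables containing planted miRNA->TF->gene feed-forward loops plus
decoy edges.  Ground truth is always emitted alongside the data; no
pipeline stage reads it.

The exact-count tripartite constructor can reproduce a regulatory network
with prescribed per-class node counts and per-type edge counts in which
every node and every edge participates in at least one feed-forward loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import GeneSetLibrary
from .ffl_mining import enumerate_ffls
from .meta_deg import ExpressionStudy

logger = logging.getLogger(__name__)

REG_EDGE_COLUMNS = [
    "source", "target", "edge_type", "species", "dialect",
    "score", "region", "binding_gap", "confidence_flag",
    "upstream_bp", "evidence_p",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults reproduce the desk-scale fixture: two studies of 10 cases vs
    10 controls over 500 genes with 25 up- and 25 down-regulated genes
    planted at |log2FC| = 1.5 against Gaussian noise of SD 0.5, and a
    regulatory layer of 26 miRNAs, 20 TFs and 5 target genes.
    """

    n_genes: int = 500
    n_case: int = 10
    n_control: int = 10
    n_studies: int = 2
    n_de_up: int = 25
    n_de_down: int = 25
    effect_lfc: float = 1.5
    noise_sd: float = 0.5
    ppi_extra_partners: float = 4.0
    n_mirna: int = 26
    n_tf: int = 20
    n_target_genes: int = 5
    n_planted_ffl: int = 12
    decoy_edge_frac: float = 0.25
    conserved_frac: float = 0.8
    seed: int = 7

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes, "n_case": self.n_case,
            "n_control": self.n_control, "n_studies": self.n_studies,
            "n_de_up": self.n_de_up, "n_de_down": self.n_de_down,
            "n_mirna": self.n_mirna, "n_tf": self.n_tf,
            "n_target_genes": self.n_target_genes,
            "n_planted_ffl": self.n_planted_ffl,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.n_de_up + self.n_de_down > self.n_genes:
            raise ValueError("n_de_up + n_de_down exceeds n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for name in ("decoy_edge_frac", "conserved_frac"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.ppi_extra_partners < 0:
            raise ValueError("ppi_extra_partners must be >= 0")
        if self.n_planted_ffl > self.n_mirna * self.n_tf * self.n_target_genes:
            raise ValueError("n_planted_ffl exceeds the number of possible triples")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# expression


def gen_expression(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> tuple[list[ExpressionStudy], pd.DataFrame]:
    """Two-study log2 expression with planted additive effects.

    Baseline per-gene means are drawn once from Normal(7, 2) — the range
    of RMA-normalized log2 intensities — and shared across studies.
    Planted up/down genes receive +/- ``effect_lfc`` on the case means in
    every study; i.i.d. Gaussian noise of SD ``noise_sd`` is added on top.
    Returns the studies and the ground-truth table (gene, direction).
    """
    if spec.n_case < 2 or spec.n_control < 2:
        raise ValueError("need >= 2 case and >= 2 control samples per study")
    rng = spec.rng() if rng is None else rng

    width = len(str(max(spec.n_genes - 1, 1)))
    genes = [f"G{i:0{width}d}" for i in range(spec.n_genes)]
    up = genes[: spec.n_de_up]
    down = genes[spec.n_de_up: spec.n_de_up + spec.n_de_down]
    effect = np.zeros(spec.n_genes)
    effect[: spec.n_de_up] = spec.effect_lfc
    effect[spec.n_de_up: spec.n_de_up + spec.n_de_down] = -spec.effect_lfc

    baseline = rng.normal(7.0, 2.0, size=spec.n_genes)
    studies = []
    for s in range(spec.n_studies):
        sid = f"study{s + 1}"
        case_cols = [f"{sid}_case{i + 1}" for i in range(spec.n_case)]
        ctrl_cols = [f"{sid}_ctrl{i + 1}" for i in range(spec.n_control)]
        case = (baseline[:, None] + effect[:, None]
                + rng.normal(0.0, spec.noise_sd, (spec.n_genes, spec.n_case)))
        ctrl = (baseline[:, None]
                + rng.normal(0.0, spec.noise_sd, (spec.n_genes, spec.n_control)))
        data = pd.DataFrame(
            np.hstack([case, ctrl]), index=pd.Index(genes, name="gene"),
            columns=case_cols + ctrl_cols)
        groups = pd.Series(
            ["case"] * spec.n_case + ["control"] * spec.n_control,
            index=data.columns)
        studies.append(ExpressionStudy(study_id=sid, data=data, groups=groups))

    truth = pd.DataFrame(
        {"gene": up + down,
         "direction": ["up"] * len(up) + ["down"] * len(down)})
    return studies, truth


def gen_probe_matrix(
    study: ExpressionStudy,
    n_multi_probe: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand a gene-level matrix to probe level.

    The first ``n_multi_probe`` genes get two probes carrying the gene's
    values verbatim (so the collapse average restores them exactly); the
    rest get one probe.  Returns (probe matrix, probe->gene map).
    """
    rows, probes, mapping = [], [], []
    for j, gene in enumerate(study.genes):
        n_probes = 2 if j < n_multi_probe else 1
        for k in range(n_probes):
            probe = f"p{k + 1}_{gene}"
            probes.append(probe)
            rows.append(study.data.loc[gene].to_numpy())
            mapping.append({"probe": probe, "gene": gene})
    matrix = pd.DataFrame(
        np.vstack(rows), index=pd.Index(probes, name="probe"),
        columns=study.data.columns)
    return matrix, pd.DataFrame(mapping)


# ---------------------------------------------------------------------------
# gene sets


def gen_gene_sets(
    spec: SyntheticSpec,
    truth: pd.DataFrame,
    rng: np.random.Generator,
    n_enriched_sets: int = 4,
    n_background_sets: int = 6,
    set_size: int = 12,
) -> list[GeneSetLibrary]:
    """GMT libraries containing sets enriched for the planted genes.

    Two libraries emulate pathway and GO-term collections: each enriched
    set draws most members from the planted DEGs (alternating up/down)
    plus a few background genes; background sets are uniform draws from
    the non-planted genes.
    """
    width = len(str(max(spec.n_genes - 1, 1)))
    all_genes = np.array([f"G{i:0{width}d}" for i in range(spec.n_genes)])
    planted_up = truth.loc[truth["direction"] == "up", "gene"].to_numpy()
    planted_down = truth.loc[truth["direction"] == "down", "gene"].to_numpy()
    background = np.array(sorted(set(all_genes) - set(truth["gene"])))

    libraries = []
    for lib_name in ("pathways", "go_terms"):
        sets: dict[str, frozenset] = {}
        for i in range(n_enriched_sets):
            pool = planted_up if i % 2 == 0 else planted_down
            if pool.size == 0:
                pool = background
            n_sig = min(set_size - 4, pool.size)
            members = set(rng.choice(pool, size=n_sig, replace=False))
            members |= set(rng.choice(background, size=set_size - n_sig,
                                      replace=False))
            sets[f"{lib_name}_enriched_{i + 1}"] = frozenset(members)
        for i in range(n_background_sets):
            members = rng.choice(background, size=min(set_size, background.size),
                                 replace=False)
            sets[f"{lib_name}_background_{i + 1}"] = frozenset(members)
        libraries.append(GeneSetLibrary(library_name=lib_name, sets=sets))
    return libraries


# ---------------------------------------------------------------------------
# PPI


def gen_ppi(
    seed_genes,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    n_designated_hubs: int = 3,
    n_below_threshold: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """BioGRID-like and HIPPIE-like PPI edge tables around seed genes.

    Seeds are joined into a clique so that every seed outranks its leaf
    interactors under all five centralities with a wide margin (hub
    calling is then insensitive to EPC Monte-Carlo noise).  The first
    ``n_designated_hubs`` seeds additionally receive three times the mean
    interactor count.  With ``ppi_extra_partners > 0`` every seed gets at
    least one private partner; at 0 only seed-seed edges are produced.
    ``n_below_threshold`` extra edges deliberately fail the
    evidence/score filters (evidence_count 0, score < 0.63) to exercise
    them.
    """
    seeds = sorted(set(seed_genes))
    if not seeds:
        raise ValueError("seed_genes must be non-empty")
    hubs = seeds[:n_designated_hubs]
    biogrid_rows, hippie_rows = [], []
    counter = 0

    def emit(u: str, v: str, passing: bool = True) -> None:
        nonlocal counter
        # alternate edges between the two table dialects
        if counter % 2 == 0:
            evidence = int(rng.integers(1, 5)) if passing else 0
            biogrid_rows.append(
                {"partner_a": u, "partner_b": v, "evidence_count": evidence})
        else:
            score = float(rng.uniform(0.63, 1.0)) if passing \
                else float(rng.uniform(0.0, 0.6299))
            hippie_rows.append(
                {"partner_a": u, "partner_b": v, "score": round(score, 4)})
        counter += 1

    for i, a in enumerate(seeds):
        for b in seeds[i + 1:]:
            emit(a, b)
    for seed in seeds:
        mean = spec.ppi_extra_partners * (3.0 if seed in hubs else 1.0)
        if mean > 0:
            n_partners = max(1, int(rng.poisson(mean)))
        else:
            n_partners = 0
        for k in range(n_partners):
            emit(seed, f"INT_{seed}_{k + 1}")
    for k in range(n_below_threshold):
        seed = seeds[int(rng.integers(0, len(seeds)))]
        emit(seed, f"WEAK_{k + 1}", passing=False)

    biogrid = pd.DataFrame(biogrid_rows,
                           columns=["partner_a", "partner_b", "evidence_count"])
    hippie = pd.DataFrame(hippie_rows, columns=["partner_a", "partner_b", "score"])
    return biogrid, hippie


# ---------------------------------------------------------------------------
# regulatory layer


def _exact_tripartite(
    n_mirna: int, n_tf: int, n_gene: int,
    e_mg: int, e_tg: int, e_mt: int,
) -> dict[str, list[tuple[int, int]]]:
    """Index-level tripartite edge sets with exact per-type counts.

    Constructs miRNA->gene, TF->gene and miRNA->TF edge lists such that
    every node and every edge participates in at least one feed-forward
    loop.  Gene 0 acts as a shared anchor: every miRNA targets it and most
    TFs do, which makes any miRNA-TF pair drawn from the anchored TF pool
    a motif edge.  Raises ``ValueError`` with the violated constraint when
    the requested counts are infeasible.
    """
    if min(n_mirna, n_tf, n_gene) < 1:
        raise ValueError("need at least one node per class")
    if n_tf < n_gene:
        raise ValueError(
            f"need n_tf >= n_gene so each gene gets a dedicated TF "
            f"(n_tf={n_tf}, n_gene={n_gene})")
    lo_mg = n_mirna + max(0, n_gene - 1)
    if not (lo_mg <= e_mg <= n_mirna * n_gene):
        raise ValueError(
            f"e_mg must lie in [{lo_mg}, {n_mirna * n_gene}], got {e_mg}")
    if not (n_tf <= e_tg <= n_tf * n_gene):
        raise ValueError(f"e_tg must lie in [{n_tf}, {n_tf * n_gene}], got {e_tg}")

    # miRNA->gene: every miRNA targets gene 0; extras cycle over the other
    # genes so each is covered.
    mg = [(m, 0) for m in range(n_mirna)]
    extras_mg = e_mg - n_mirna
    if n_gene > 1:
        for i in range(extras_mg):
            mg.append((i % n_mirna, (i % (n_gene - 1)) + 1))
    mg = list(dict.fromkeys(mg))
    if len(mg) != e_mg:
        raise ValueError("e_mg too large for distinct miRNA->gene pairs "
                         "under the anchored construction")

    # TF->gene: TFs 0..n_gene-2 cover genes 1..n_gene-1, the rest target
    # gene 0; extras first anchor the gene-covering TFs to gene 0.
    tg = [(j, j + 1) for j in range(n_gene - 1)]
    tg += [(j, 0) for j in range(n_gene - 1, n_tf)]
    extras_tg = e_tg - n_tf
    pool = [(j, 0) for j in range(n_gene - 1)]
    pool += [(j, g) for j in range(n_tf) for g in range(1, n_gene)
             if (j, g) not in set(tg)]
    if extras_tg > len(pool):
        raise ValueError("e_tg too large for distinct TF->gene pairs")
    tg += pool[:extras_tg]

    tg_set = set(tg)
    anchored_tfs = sorted({j for (j, g) in tg_set if g == 0})

    # required miRNA->TF pairs: every non-anchor gene's miRNAs and TFs
    # must meet at least once over that gene
    mirnas_of = {g: sorted(m for (m, gg) in mg if gg == g) for g in range(n_gene)}
    tfs_of = {g: sorted(j for (j, gg) in tg_set if gg == g) for g in range(n_gene)}
    mt: list[tuple[int, int]] = []
    for g in range(1, n_gene):
        a0, b0 = mirnas_of[g][0], tfs_of[g][0]
        mt += [(m, b0) for m in mirnas_of[g]]
        mt += [(a0, j) for j in tfs_of[g]]
    # coverage: every TF and every miRNA in >= 1 miRNA->TF edge
    covered_t = {j for (_, j) in mt}
    for j in range(n_tf):
        if j not in covered_t:
            mt.append((j % n_mirna, j))
    covered_m = {m for (m, _) in mt}
    for m in range(n_mirna):
        if m not in covered_m:
            mt.append((m, anchored_tfs[m % len(anchored_tfs)]))
    mt = list(dict.fromkeys(mt))
    if len(mt) > e_mt:
        raise ValueError(
            f"e_mt={e_mt} below the {len(mt)} pairs required for coverage")

    # fill with pairs over the anchored TF pool (always motif edges)
    existing = set(mt)
    for j in anchored_tfs:
        for m in range(n_mirna):
            if len(mt) == e_mt:
                break
            if (m, j) not in existing:
                mt.append((m, j))
                existing.add((m, j))
        if len(mt) == e_mt:
            break
    if len(mt) < e_mt:
        raise ValueError(
            f"e_mt={e_mt} exceeds the {len(mt)} constructible motif pairs")
    return {"mirna_gene": mg, "tf_gene": tg, "mirna_tf": mt}


def _edge_row(source: str, target: str, edge_type: str, species: str,
              dialect: str, rng: np.random.Generator,
              passing: bool = True) -> dict:
    row = {c: np.nan for c in REG_EDGE_COLUMNS}
    row.update(source=source, target=target, edge_type=edge_type,
               species=species, dialect=dialect)
    if dialect == "mirwalk":
        row["score"] = round(float(rng.uniform(0.95, 1.0)), 4) if passing \
            else round(float(rng.uniform(0.5, 0.9499)), 4)
        row["region"] = "3UTR" if passing else "CDS"
        row["binding_gap"] = 1
    elif dialect == "starbase":
        row["score"] = round(float(rng.uniform(0.95, 1.0)), 4) if passing \
            else round(float(rng.uniform(0.5, 0.9499)), 4)
    elif dialect == "mirsearch":
        row["confidence_flag"] = "high" if passing else "low"
    elif dialect == "chipbase":
        row["upstream_bp"] = int(rng.integers(1, 1001)) if passing \
            else int(rng.integers(1001, 5000))
    elif dialect == "enrichr_tf":
        row["evidence_p"] = round(float(rng.uniform(1e-6, 0.0499)), 6) if passing \
            else round(float(rng.uniform(0.05, 1.0)), 6)
    elif dialect == "itfp":
        pass
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return row


_MIRNA_DIALECT_CYCLE = ("mirwalk", "starbase", "mirsearch")
_TF_DIALECT_CYCLE = ("chipbase", "itfp", "enrichr_tf")


def _dialect_for(edge_type: str, index: int) -> str:
    if edge_type in ("mirna_gene", "mirna_tf"):
        return _MIRNA_DIALECT_CYCLE[index % 3]
    return _TF_DIALECT_CYCLE[index % 3]


def gen_regulatory(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    target_genes: list[str] | None = None,
    exact_counts: tuple[int, int, int] | None = None,
    allow_accidental: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Human and mouse regulatory edge tables with planted FFLs.

    Plants ``spec.n_planted_ffl`` triples (miRNA, TF, gene) whose three
    edges all pass the source-specific filters, then adds decoy edges —
    ``decoy_edge_frac`` of the planted edge count with passing scores,
    rejection-sampled so they never complete an unplanted loop (disable
    with ``allow_accidental``), plus the same number with failing scores
    to exercise the filters.  A ``conserved_frac`` fraction of human
    miRNAs is mirrored into the mouse table ("mmu-" prefix).

    With ``exact_counts=(e_mg, e_tg, e_mt)`` the deterministic anchored
    construction is used instead: every node and edge sits in >= 1 loop
    and the per-type edge counts are reproduced exactly (all edges
    passing, fully conserved).

    Returns (human edges, mouse edges, ground-truth FFL list).
    """
    rng = spec.rng() if rng is None else rng
    mirnas = [f"hsa-miR-{100 + i}-5p" for i in range(spec.n_mirna)]
    tfs = [f"TF{i + 1:02d}" for i in range(spec.n_tf)]
    if target_genes is None:
        genes = [f"HUB{i + 1}" for i in range(spec.n_target_genes)]
    else:
        genes = list(target_genes)
        if len(genes) != spec.n_target_genes:
            raise ValueError(
                f"target_genes has {len(genes)} entries, spec wants "
                f"{spec.n_target_genes}")

    if exact_counts is not None:
        idx_edges = _exact_tripartite(
            spec.n_mirna, spec.n_tf, spec.n_target_genes, *exact_counts)
        typed = []
        for edge_type, pairs in idx_edges.items():
            for i, (a, b) in enumerate(pairs):
                if edge_type == "mirna_gene":
                    s, t = mirnas[a], genes[b]
                elif edge_type == "mirna_tf":
                    s, t = mirnas[a], tfs[b]
                else:
                    s, t = tfs[a], genes[b]
                typed.append((s, t, edge_type, i))
        human = pd.DataFrame(
            [_edge_row(s, t, et, "human", _dialect_for(et, i), rng)
             for (s, t, et, i) in typed],
            columns=REG_EDGE_COLUMNS)
        mouse = _mirror_mouse(human, frac=1.0, rng=rng)
        truth = enumerate_ffls(
            human[["source", "target", "edge_type"]].drop_duplicates())
        return human, mouse, truth

    # --- planted random triples -------------------------------------------
    edges: dict[tuple[str, str, str], bool] = {}
    planted: list[tuple[str, str, str]] = []

    def loop_count() -> int:
        if not edges:
            return 0
        frame = pd.DataFrame(
            [(s, t, et) for (s, t, et) in edges],
            columns=["source", "target", "edge_type"])
        return len(enumerate_ffls(frame))

    attempts = 0
    while len(planted) < spec.n_planted_ffl:
        attempts += 1
        if attempts > 200 * max(spec.n_planted_ffl, 1):
            raise ValueError(
                "could not place the requested planted FFLs without "
                "accidental loops; lower n_planted_ffl or enlarge the node classes")
        m = mirnas[int(rng.integers(spec.n_mirna))]
        t = tfs[int(rng.integers(spec.n_tf))]
        g = genes[int(rng.integers(spec.n_target_genes))]
        if (m, t, g) in planted:
            continue
        candidate = {(m, t, "mirna_tf"), (m, g, "mirna_gene"), (t, g, "tf_gene")}
        before = loop_count()
        for key in candidate:
            edges.setdefault(key, True)
        if not allow_accidental and loop_count() != before + 1:
            for key in candidate:
                if key not in {e for p in planted for e in _triple_edges(p)}:
                    edges.pop(key, None)
            continue
        planted.append((m, t, g))

    n_decoy = int(round(spec.decoy_edge_frac * 3 * spec.n_planted_ffl))
    placed = 0
    attempts = 0
    while placed < n_decoy and attempts < 200 * max(n_decoy, 1):
        attempts += 1
        edge_type = ("mirna_gene", "mirna_tf", "tf_gene")[int(rng.integers(3))]
        if edge_type == "mirna_gene":
            s, t = mirnas[int(rng.integers(spec.n_mirna))], genes[int(rng.integers(spec.n_target_genes))]
        elif edge_type == "mirna_tf":
            s, t = mirnas[int(rng.integers(spec.n_mirna))], tfs[int(rng.integers(spec.n_tf))]
        else:
            s, t = tfs[int(rng.integers(spec.n_tf))], genes[int(rng.integers(spec.n_target_genes))]
        key = (s, t, edge_type)
        if key in edges:
            continue
        before = loop_count()
        edges[key] = True
        if not allow_accidental and loop_count() != before:
            del edges[key]
            continue
        placed += 1

    rows = [
        _edge_row(s, t, et, "human", _dialect_for(et, i), rng)
        for i, (s, t, et) in enumerate(sorted(edges))
    ]
    # failing-score rows: same size as the passing decoy set, any location
    for k in range(n_decoy):
        edge_type = ("mirna_gene", "mirna_tf", "tf_gene")[k % 3]
        if edge_type == "mirna_gene":
            s, t = mirnas[k % spec.n_mirna], genes[k % spec.n_target_genes]
        elif edge_type == "mirna_tf":
            s, t = mirnas[k % spec.n_mirna], tfs[k % spec.n_tf]
        else:
            s, t = tfs[k % spec.n_tf], genes[k % spec.n_target_genes]
        rows.append(_edge_row(s, t, edge_type, "human",
                              _dialect_for(edge_type, k), rng, passing=False))
    human = pd.DataFrame(rows, columns=REG_EDGE_COLUMNS)
    mouse = _mirror_mouse(human, frac=spec.conserved_frac, rng=rng)
    truth = pd.DataFrame(sorted(planted), columns=["mirna", "tf", "gene"])
    return human, mouse, truth


def _triple_edges(triple: tuple[str, str, str]) -> set[tuple[str, str, str]]:
    m, t, g = triple
    return {(m, t, "mirna_tf"), (m, g, "mirna_gene"), (t, g, "tf_gene")}


def _mirror_mouse(
    human: pd.DataFrame,
    frac: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Mouse table mirroring a fraction of human miRNA edges (mmu- prefix)."""
    mirna_rows = human[human["edge_type"].isin(("mirna_gene", "mirna_tf"))]
    sources = sorted(mirna_rows["source"].unique())
    n_keep = int(round(frac * len(sources)))
    if frac > 0 and sources and n_keep == 0:
        n_keep = 1
    keep = set(sources[:n_keep]) if frac >= 1.0 else set(
        rng.choice(sources, size=n_keep, replace=False)) if n_keep else set()
    mirrored = mirna_rows[mirna_rows["source"].isin(keep)].copy()
    mirrored["source"] = mirrored["source"].str.replace(
        "hsa-", "mmu-", regex=False)
    mirrored["species"] = "mouse"
    return mirrored.reset_index(drop=True)


def table1_spec() -> SyntheticSpec:
    """Spec sized to the published FFL network (26 miRNAs, 20 TFs, 5 genes)."""
    return SyntheticSpec(n_mirna=26, n_tf=20, n_target_genes=5,
                         conserved_frac=1.0)


TABLE1_EDGE_COUNTS = (32, 21, 144)  # miRNA-gene, TF-gene, miRNA-TF


def gen_table1_regulatory(
    seed: int = 7,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Regulatory tables reproducing the published per-type edge counts."""
    spec = table1_spec()
    spec = SyntheticSpec(**{**spec.__dict__, "seed": seed})
    return gen_regulatory(spec, exact_counts=TABLE1_EDGE_COUNTS)
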