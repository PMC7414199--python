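"""End-to-end orchestration of the five analysis stages.

``run_pipeline`` chains expression loading, the DEG meta-analysis,
gene-set over-representation, PPI hub calling and feed-forward-loop
mining, writing every stage's report as tab-separated text plus a
manifest.  Output is a pure function of (inputs, config, rng_seed):
identical runs produce byte-identical files.

``generate_bundle`` writes a complete synthetic input bundle (expression,
annotation, probe map, GMT libraries, PPI tables, regulatory tables and
the ground truth) under a versioned per-seed directory.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import ffl_mining as ffl
from . import io as fio
from . import meta_deg as md
from . import ppi_hubs as ph
from . import synthetic as syn
from .config import PipelineConfig

logger = logging.getLogger(__name__)

STAGES = ("expression", "meta_deg", "enrichment", "ppi_hubs", "ffl_mining")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _designated_hubs(truth: pd.DataFrame, n_up: int = 3, n_down: int = 2) -> list[str]:
    up = sorted(truth.loc[truth["direction"] == "up", "gene"])[:n_up]
    down = sorted(truth.loc[truth["direction"] == "down", "gene"])[:n_down]
    return up + down


def generate_bundle(spec: syn.SyntheticSpec, outdir: str | Path) -> Path:
    """Write every pipeline input for ``spec`` under ``<outdir>/bundle_seed<N>``."""
    bundle = Path(outdir) / f"bundle_seed{spec.seed}"
    bundle.mkdir(parents=True, exist_ok=True)
    rng = spec.rng()

    studies, truth = syn.gen_expression(spec, rng)
    probe_frames, probe_maps = [], []
    for study in studies:
        matrix, mapping = syn.gen_probe_matrix(study)
        probe_frames.append(matrix)
        probe_maps.append(mapping)
    probe_matrix = pd.concat(probe_frames, axis=1)
    probe_matrix = probe_matrix.loc[:, ~probe_matrix.columns.duplicated()]
    fio.write_table(probe_matrix, bundle / "expression.tsv", index=True)
    ann = pd.concat([
        pd.DataFrame({"sample": s.samples, "study_id": s.study_id,
                      "group": s.groups.to_numpy()})
        for s in studies
    ])
    fio.write_table(ann, bundle / "annotation.tsv")
    fio.write_table(probe_maps[0], bundle / "probe_map.tsv")
    fio.write_table(truth, bundle / "truth_degs.tsv")

    for library in syn.gen_gene_sets(spec, truth, rng):
        fio.write_gmt(library, bundle / f"{library.library_name}.gmt")

    hubs = _designated_hubs(truth)
    up_seeds = sorted(truth.loc[truth["direction"] == "up", "gene"])
    down_seeds = sorted(truth.loc[truth["direction"] == "down", "gene"])
    bg_parts, hp_parts = [], []
    for seeds in (up_seeds, down_seeds):
        if seeds:
            bg, hp = syn.gen_ppi(seeds, spec, rng)
            bg_parts.append(bg)
            hp_parts.append(hp)
    fio.write_table(pd.concat(bg_parts, ignore_index=True) if bg_parts
                    else pd.DataFrame(columns=["partner_a", "partner_b",
                                               "evidence_count"]),
                    bundle / "biogrid.tsv")
    fio.write_table(pd.concat(hp_parts, ignore_index=True) if hp_parts
                    else pd.DataFrame(columns=["partner_a", "partner_b", "score"]),
                    bundle / "hippie.tsv")

    reg_spec = syn.SyntheticSpec(**{**spec.__dict__,
                                    "n_target_genes": len(hubs)})
    human, mouse, truth_ffl = syn.gen_regulatory(reg_spec, rng,
                                                 target_genes=hubs)
    fio.write_table(human, bundle / "regulatory_human.tsv")
    fio.write_table(mouse, bundle / "regulatory_mouse.tsv")
    fio.write_table(truth_ffl, bundle / "truth_ffls.tsv")
    logger.info("generate_bundle: wrote %s", bundle)
    return bundle


def bundle_inputs(bundle: str | Path) -> dict:
    """Input-path mapping for a bundle written by ``generate_bundle``."""
    bundle = Path(bundle)
    return {
        "expression": bundle / "expression.tsv",
        "annotation": bundle / "annotation.tsv",
        "probe_map": bundle / "probe_map.tsv",
        "gmt": sorted(bundle.glob("*.gmt")),
        "ppi": [bundle / "biogrid.tsv", bundle / "hippie.tsv"],
        "reg_human": bundle / "regulatory_human.tsv",
        "reg_mouse": bundle / "regulatory_mouse.tsv",
    }


def _write_topology(stats: dict, outdir: Path) -> list[Path]:
    paths = []

    def write(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        path = outdir / name
        fio.write_table(frame, path, index=index)
        paths.append(path)

    write("ffl_topology_nodes.tsv", stats["node_table"], index=True)
    for key, cols in (
            ("degree_histogram", ("degree", "n_nodes")),
            ("clustering_by_degree", ("degree", "mean_clustering")),
            ("topological_by_degree", ("degree", "mean_topological_coefficient")),
            ("path_length_histogram", ("distance", "n_pairs"))):
        frame = pd.DataFrame(sorted(stats[key].items()), columns=list(cols))
        write(f"ffl_{key}.tsv", frame)
    fit = stats["power_law_fit"]
    write("ffl_power_law_fit.tsv", pd.DataFrame([fit]))
    return paths


def run_pipeline(
    config: PipelineConfig,
    inputs: dict,
    outdir: str | Path,
) -> dict:
    """Run all stages; returns a result bundle of in-memory objects.

    ``inputs`` maps: ``expression``, ``annotation``, optional
    ``probe_map``, ``gmt`` (list of GMT paths), ``ppi`` (list of PPI edge
    tables, dialects auto-detected), ``reg_human``, ``reg_mouse``.
    Reports land in ``outdir`` together with ``manifest.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    result: dict = {}

    def record(stage: str, *paths: Path) -> None:
        for path in paths:
            manifest.append({"stage": stage, "output": path.name})

    # --- stage 1: expression ---------------------------------------------
    stage = "expression"
    try:
        studies = fio.read_expression(inputs["expression"], inputs["annotation"])
        if inputs.get("probe_map"):
            probe_map = fio.read_probe_map(inputs["probe_map"])
            studies = [md.collapse_probes(s, probe_map) for s in studies]
        logger.info("expression: %d studies, %d genes",
                    len(studies), len(studies[0].genes))
        counts = pd.DataFrame([
            {"study_id": s.study_id, "n_genes": len(s.genes),
             "n_case": s.n_case, "n_control": s.n_control}
            for s in studies])
        path = outdir / "expression_summary.tsv"
        fio.write_table(counts, path)
        record(stage, path)
        result["studies"] = studies
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- stage 2: meta-analysis ------------------------------------------
    stage = "meta_deg"
    try:
        deg_table, study_specific = md.meta_analyze(
            studies, test_mode=config.test_mode)
        up, down = md.screen_degs(deg_table, config.de_alpha, config.lfc_cut)
        deg_path = outdir / "deg_table.tsv"
        fio.write_table(deg_table, deg_path, index=True)
        up_path = outdir / "degs_up.tsv"
        fio.write_table(pd.DataFrame({"gene": up}), up_path)
        down_path = outdir / "degs_down.tsv"
        fio.write_table(pd.DataFrame({"gene": down}), down_path)
        ss_path = outdir / "study_specific_genes.tsv"
        fio.write_table(study_specific, ss_path)
        record(stage, deg_path, up_path, down_path, ss_path)
        result.update(deg_table=deg_table, degs_up=up, degs_down=down)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- stage 3: enrichment ---------------------------------------------
    stage = "enrichment"
    try:
        universe = set(studies[0].genes)
        for s in studies[1:]:
            universe |= set(s.genes)
        query = sorted(set(up) | set(down))
        if not query:
            raise ValueError("no DEGs passed the screen; nothing to enrich")
        results = []
        paths = []
        for gmt_path in inputs["gmt"]:
            library = fio.read_gmt(gmt_path)
            res = enr.fisher_enrich(query, library, universe,
                                    config.enrich_alpha)
            results.append(res)
            path = outdir / f"enrichment_{library.library_name}.tsv"
            fio.write_table(res, path)
            paths.append(path)
        union = enr.enriched_union(results, query)
        direction = deg_table["direction"]
        union_frame = pd.DataFrame({
            "gene": sorted(union),
            "regulation": [direction.get(g, "none") for g in sorted(union)],
        })
        union_path = outdir / "enriched_union.tsv"
        fio.write_table(union_frame, union_path)
        member_path = outdir / "pathway_membership.tsv"
        fio.write_table(enr.membership_table(results), member_path)
        record(stage, *paths, union_path, member_path)
        result.update(enrichment=results, enriched_union=union_frame)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- stage 4: PPI hubs -------------------------------------------------
    stage = "ppi_hubs"
    try:
        biogrid_parts, hippie_parts = [], []
        for path in inputs["ppi"]:
            dialect, frame = fio.read_ppi_table(path)
            (biogrid_parts if dialect == "biogrid" else hippie_parts).append(frame)
        biogrid = pd.concat(biogrid_parts, ignore_index=True) if biogrid_parts else None
        hippie = pd.concat(hippie_parts, ignore_index=True) if hippie_parts else None
        rng = np.random.default_rng(config.rng_seed)

        hub_sets: dict[str, set] = {}
        regulation_map = dict(zip(union_frame["gene"], union_frame["regulation"]))
        paths = []
        for reg in ("up", "down"):
            seeds = sorted(union_frame.loc[union_frame["regulation"] == reg,
                                           "gene"])
            if not seeds:
                logger.warning("ppi_hubs: no %sregulated enriched seeds", reg)
                hub_sets[reg] = set()
                continue
            graph = ph.build_ppi(seeds, biogrid, hippie, config,
                                 regulation=regulation_map)
            cent = ph.compute_centralities(graph, config, rng)
            seeds_in_network = [s for s in seeds if s in graph]
            n = (len(seeds_in_network) if config.top_n_mode == "n_seed_degs"
                 else config.explicit_top_n)
            hubs = ph.identify_hubs(cent, n=max(n, 1), seed_genes=seeds)
            hub_sets[reg] = hubs
            node_path = outdir / f"ppi_nodes_{reg}.tsv"
            fio.write_table(cent, node_path, index=True)
            edge_frame = pd.DataFrame(
                [{"partner_a": u, "partner_b": v,
                  "provenance": ";".join(sorted(d["provenance"]))}
                 for u, v, d in graph.edges(data=True)]
            ).sort_values(["partner_a", "partner_b"]).reset_index(drop=True) \
                if graph.number_of_edges() else pd.DataFrame(
                    columns=["partner_a", "partner_b", "provenance"])
            edge_path = outdir / f"ppi_edges_{reg}.tsv"
            fio.write_table(edge_frame, edge_path)
            paths += [node_path, edge_path]
        hubs_frame = pd.DataFrame(
            [{"gene": g, "regulation": reg}
             for reg in ("up", "down") for g in sorted(hub_sets[reg])])
        hub_path = outdir / "hub_genes.tsv"
        fio.write_table(hubs_frame, hub_path)
        record(stage, *paths, hub_path)
        result.update(hub_genes=hubs_frame)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- stage 5: FFL mining ----------------------------------------------
    stage = "ffl_mining"
    try:
        human = fio.read_reg_edges(inputs["reg_human"])
        mouse = fio.read_reg_edges(inputs["reg_mouse"])
        human_f = ffl.filter_edges(human, config)
        mouse_f = ffl.filter_edges(mouse, config)
        hub_genes = set(hubs_frame["gene"])
        gene_edge = human_f["edge_type"].isin(("mirna_gene", "tf_gene"))
        human_f = human_f[~gene_edge | human_f["target"].isin(hub_genes)]
        final_mirnas, conserved = ffl.conservation_filter(human_f, mouse_f)
        motifs = ffl.enumerate_ffls(conserved)
        network = ffl.build_ffl_network(motifs)

        motif_path = outdir / "ffl_motifs.tsv"
        fio.write_table(motifs, motif_path)
        edge_path = outdir / "ffl_edges.tsv"
        fio.write_table(network.edges, edge_path)
        node_frame = pd.DataFrame(
            [{"node": n, "node_class": cls}
             for cls, nodes in (("mirna", network.mirnas), ("tf", network.tfs),
                                ("gene", network.genes))
             for n in nodes])
        node_path = outdir / "ffl_nodes.tsv"
        fio.write_table(node_frame, node_path)
        summary_path = outdir / "ffl_summary.tsv"
        fio.write_table(network.summary_table(), summary_path)
        paths = [motif_path, edge_path, node_path, summary_path]
        if network.n_nodes:
            stats = ffl.topology_stats(network)
            paths += _write_topology(stats, outdir)
            result["topology"] = stats
        record(stage, *paths)
        result.update(ffl_network=network, final_mirnas=final_mirnas)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    manifest_frame = pd.DataFrame(manifest, columns=["stage", "output"])
    fio.write_table(manifest_frame, outdir / "manifest.tsv")
    result["manifest"] = manifest_frame
    logger.info("run_pipeline: %d stages, %d reports",
                manifest_frame["stage"].nunique(), len(manifest_frame))
    return result
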