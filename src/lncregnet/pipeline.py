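"""End-to-end orchestration: simulate -> preprocess -> de -> coexpr ->
enrich -> network -> power, driven by a single YAML config, with a JSON
run manifest recording per-stage counts."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coexpression import (
    PairScreenConfig,
    chromosome_distribution,
    coexpressed_genes,
    screen_negative_pairs,
)
from .diffexpr import (
    ThresholdConfig,
    differential_expression,
    select_differential,
)
from .enrichment import enrich
from .io_formats import (
    FormatError,
    read_expression_matrix,
    read_gmt,
    read_probe_annotation,
    read_sample_design,
    write_network,
    write_table,
)
from .power_analysis import PowerConfig, bootstrap_power, minimum_sample_size
from .preprocess import FilterRule, preprocess
from .synthetic import SimulationConfig, simulate_dataset, write_dataset
from .tf_network import (
    associate_tfs,
    build_lncrna_tf_gene_network,
    build_lncrna_tf_network,
    network_summary,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ["simulate", "preprocess", "de", "coexpr", "enrich", "network", "power"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    known = set(ALL_STAGES) | {"seed", "outdir", "stages", "input"}
    unknown = set(cfg) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def summarize_counts(de_results: pd.DataFrame | None = None,
                     de_selected: dict[str, tuple[pd.DataFrame, pd.DataFrame]] | None = None,
                     pairs: pd.DataFrame | None = None,
                     per_chromosome: dict[str, int] | None = None) -> dict:
    """Results-style deterministic aggregation of stage outputs."""
    summary: dict = {}
    if de_selected is not None:
        de_counts = {}
        for ttype, (up, down) in de_selected.items():
            de_counts[ttype] = {"up": len(up), "down": len(down),
                                "total": len(up) + len(down)}
        summary["differential"] = de_counts
    if de_results is not None:
        summary["probes_tested"] = int((~de_results["degenerate"]).sum())
        summary["probes_degenerate"] = int(de_results["degenerate"].sum())
    if pairs is not None:
        same = pairs[pairs["same_chromosome"]] if len(pairs) else pairs
        cls = pairs["regulation_class"].value_counts().to_dict() if len(pairs) else {}
        summary["pairs"] = {
            "total": len(pairs),
            "same_chromosome": len(same),
            "cis": int(cls.get("cis", 0)),
            "trans": int(cls.get("trans", 0)),
            "unclassified": int(cls.get("unclassified", 0)),
        }
    if per_chromosome is not None:
        summary["pairs_per_chromosome"] = dict(sorted(per_chromosome.items()))
    return summary


def run_pipeline(config: dict | str | Path, outdir: str | Path,
                 seed: int | None = None) -> dict:
    """Run the configured stages in fixed order; returns the run manifest.

    All stage outputs are written under `outdir` as tab-separated tables,
    SIF/GraphML networks and the manifest JSON.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(config.get("seed", 0))
    stages = config.get("stages", ALL_STAGES)
    bad = [s for s in stages if s not in ALL_STAGES]
    if bad:
        raise ConfigError(f"unknown stages: {bad}")

    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "stages": [],
        "inputs": {},
        "counts": {},
    }

    matrix = design = annotation = None
    function_sets = tf_sets = None
    de_results = None
    de_lnc_probes: list[str] = []
    de_mrna_probes: list[str] = []
    de_selected: dict = {}
    pairs = None
    coexpr_lists: dict[str, list[str]] = {}
    universe: list[str] = []

    def record(stage: str, counts: dict) -> None:
        manifest["stages"].append(stage)
        manifest["counts"][stage] = counts

    # ----- inputs ----------------------------------------------------------
    if "simulate" in stages:
        sim_cfg = SimulationConfig.from_dict(
            {**(config.get("simulate") or {}), "seed": seed})
        dataset = simulate_dataset(sim_cfg)
        data_dir = outdir / "simulated"
        paths = write_dataset(dataset, data_dir)
        matrix, design, annotation = dataset.matrix, dataset.design, dataset.annotation
        function_sets, tf_sets = dataset.function_sets, dataset.tf_sets
        record("simulate", {
            "probes": matrix.n_probes,
            "samples": matrix.n_samples,
            "planted_de": len(dataset.truth.de_probes),
            "planted_pairs": len(dataset.truth.pairs),
            "planted_tf_modules": len(dataset.truth.tf_modules),
        })
        manifest["inputs"] = {k: _sha256(v) for k, v in paths.items()}
    else:
        inp = config.get("input")
        if not inp:
            raise ConfigError("config needs either a 'simulate' block or 'input' paths")
        matrix = read_expression_matrix(inp["matrix"], inp.get("flags"))
        design = read_sample_design(inp["design"])
        annotation = read_probe_annotation(inp["annotation"])
        if "function_gmt" in inp:
            function_sets = read_gmt(inp["function_gmt"], "function")
        if "tf_gmt" in inp:
            tf_sets = read_gmt(inp["tf_gmt"], "tf_targets")
        manifest["inputs"] = {k: _sha256(Path(v)) for k, v in inp.items()
                              if v is not None}

    # ----- preprocess ------------------------------------------------------
    if "preprocess" in stages:
        pp = config.get("preprocess") or {}
        rule = FilterRule(
            required_flag=pp.get("required_flag", "P"),
            min_fraction_per_condition=pp.get("min_fraction_per_condition", 0.5),
        )
        matrix, report = preprocess(matrix, design, rule,
                                    offset=pp.get("offset", 0.0))
        write_table(matrix.to_frame().reset_index(names="probe_id"),
                    outdir / "normalized_matrix.tsv")
        record("preprocess", report)

    # ----- differential expression ----------------------------------------
    if "de" in stages:
        de_cfg = config.get("de") or {}
        thresholds = ThresholdConfig(
            fc_min=de_cfg.get("fc_min", 2.0),
            p_max=de_cfg.get("p_max", 0.05),
            use_q=de_cfg.get("use_q", False),
            q_max=de_cfg.get("q_max", 0.05),
        )
        de_results = differential_expression(matrix, design, annotation)
        write_table(de_results, outdir / "differential_expression.tsv")
        for ttype in ("mRNA", "lncRNA"):
            up, down = select_differential(de_results, thresholds, ttype)
            de_selected[ttype] = (up, down)
        de_mrna_probes = list(pd.concat(de_selected["mRNA"])["probe_id"])
        de_lnc_probes = list(pd.concat(de_selected["lncRNA"])["probe_id"])
        record("de", summarize_counts(de_results=de_results,
                                      de_selected=de_selected))

    # ----- co-expression screen -------------------------------------------
    if "coexpr" in stages:
        cx = config.get("coexpr") or {}
        screen_cfg = PairScreenConfig(
            corr_p_max=cx.get("corr_p_max", 0.05),
            r_max=cx.get("r_max", -0.9),
            cis_window=cx.get("cis_window", 100_000),
            cis_corr_p_max=cx.get("cis_corr_p_max", 0.01),
            restrict_to_differential=cx.get("restrict_to_differential", True),
        )
        pairs = screen_negative_pairs(matrix, annotation,
                                      de_lncrna=de_lnc_probes,
                                      de_mrna=de_mrna_probes,
                                      config=screen_cfg)
        write_table(pairs, outdir / "negative_pairs.tsv")
        per_chrom = chromosome_distribution(pairs, annotation)
        record("coexpr", summarize_counts(pairs=pairs, per_chromosome=per_chrom))

    # ----- enrichment / TF network ----------------------------------------
    needs_lists = [s for s in ("enrich", "network") if s in stages]
    if needs_lists:
        en_cfg = config.get("enrich") or {}
        corr_p_max = en_cfg.get("corr_p_max", 0.05)
        in_matrix = set(matrix.probe_ids)
        seen: dict[str, None] = {}
        for p in annotation.probes_of_type("mRNA"):
            if p in in_matrix:
                seen.setdefault(annotation.symbol_of(p), None)
        universe = list(seen)
        for probe in de_lnc_probes:
            coexpr_lists[probe] = coexpressed_genes(probe, matrix, annotation,
                                                    p_max=corr_p_max)

    if "enrich" in stages:
        if function_sets is None:
            raise ConfigError("enrich stage requires function gene sets")
        enrich_dir = outdir / "enrichment"
        enrich_dir.mkdir(exist_ok=True)
        n_tables = 0
        for probe, genes in coexpr_lists.items():
            if not genes:
                continue
            table = enrich(genes, function_sets, universe)
            write_table(table, enrich_dir / f"{probe}.tsv")
            n_tables += 1
        record("enrich", {"lncrnas_tested": len(coexpr_lists),
                          "tables_written": n_tables,
                          "sets": len(function_sets)})

    if "network" in stages:
        if tf_sets is None:
            raise ConfigError("network stage requires TF target gene sets")
        net_cfg = config.get("network") or {}
        associations = associate_tfs(coexpr_lists, tf_sets, universe,
                                     q_max=net_cfg.get("q_max", 0.05))
        write_table(associations, outdir / "tf_associations.tsv")
        bipartite = build_lncrna_tf_network(associations)
        tripartite = build_lncrna_tf_gene_network(associations, tf_sets,
                                                  coexpr_lists)
        write_network(bipartite, outdir / "lncrna_tf.sif", "SIF")
        write_network(bipartite, outdir / "lncrna_tf.graphml", "GraphML")
        write_network(tripartite, outdir / "lncrna_tf_gene.sif", "SIF")
        write_network(tripartite, outdir / "lncrna_tf_gene.graphml", "GraphML")
        record("network", {
            "associations": len(associations),
            "lncrna_tf": network_summary(bipartite),
            "lncrna_tf_gene": network_summary(tripartite),
        })

    # ----- power -----------------------------------------------------------
    if "power" in stages:
        pw = config.get("power") or {}
        target_genes = pw.get("target_genes")
        if not target_genes:
            # default: strongest selected differential mRNAs
            if de_results is None:
                raise ConfigError("power stage needs target_genes or a de stage")
            sel = pd.concat(de_selected["mRNA"]) if de_selected else pd.DataFrame()
            sel = sel.sort_values("p_value").head(5)
            target_genes = list(sel["gene_symbol"])
        power_cfg = PowerConfig(
            sample_sizes=pw.get("sample_sizes", [3, 4, 5]),
            n_bootstrap=pw.get("n_bootstrap", 200),
            detection=ThresholdConfig(
                fc_min=pw.get("fc_min", 2.0),
                use_q=True,
                q_max=pw.get("q_max", 0.5),
            ),
            target_genes=list(target_genes),
            power_threshold=pw.get("power_threshold", 0.8),
            seed=seed,
        )
        curve = bootstrap_power(matrix, design, annotation, power_cfg)
        write_table(curve, outdir / "power_curve.tsv")
        minima = minimum_sample_size(curve, power_cfg.power_threshold)
        record("power", {
            "genes": len(power_cfg.target_genes),
            "sample_sizes": list(power_cfg.sample_sizes),
            "minimum_sample_size": minima,
        })

    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
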