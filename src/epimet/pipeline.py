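"""End-to-end pipeline orchestration from a single YAML config.

Stages: per-cohort DMS calling (default contrast: lung metastases vs pooled
primary tumors + lymph-node metastases) → probe annotation → per-gene
promoter DMS counts and methylation classes → cross-cohort concordance →
expression integration (external DE table, or the labelled stand-in test on
a counts matrix) → chromosome / CpG-context / chromatin-state enrichments →
optional gene-set over-representation → top-k variable-site Spearman distance
trees. All stage tables are written as TSV; a run manifest records the seed,
thresholds, package version and per-stage record counts. Outputs are
deterministic: the same config and seed reproduce byte-identical bundles.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io_formats
from .dms_calling import Contrast, call_dms, top_variable_sites
from .enrichment_stats import chromosome_enrichment, context_enrichment, ora
from .gene_integration import (
    classify_genes,
    concordance_filter,
    de_genes,
    filter_low_expression,
    integrate,
    standin_de_test,
)
from .genomic_annotation import (
    assign_probes,
    build_promoters,
    count_promoter_dms,
    write_probe_annotation,
)
from .io_formats import ValidationError
from .methylome_distance import cluster_tree, spearman_distance
from .synthetic_cohort import SimulationConfig, simulate_cohorts, write_simulation

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "delta_beta": 0.15,
    "p_value": 0.05,
    "use_q": False,
    "lfc": 1.0,
    "de_p": 0.05,
    "min_base_mean": 20.0,
    "top_k": 5000,
}

DEFAULT_CONTRASTS = {
    "methylation": {"target": ["LU"], "reference": ["PT", "LN"]},
    "expression": {"target": "LU", "reference": ["PT"]},
}


def load_pipeline_config(path) -> dict:
    """Load and validate a pipeline YAML config; fill threshold defaults.

    Relative input paths are resolved against the config file's directory.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = dict(raw)
    cfg.setdefault("seed", 0)
    thresholds = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    for key in ("delta_beta", "p_value", "lfc", "de_p", "top_k"):
        if thresholds[key] <= 0:
            raise ValidationError(f"threshold {key} must be positive")
    cfg["thresholds"] = thresholds
    cfg["contrasts"] = {**DEFAULT_CONTRASTS, **cfg.get("contrasts", {})}
    if "cohorts" not in cfg or len(cfg["cohorts"]) < 2:
        raise ValidationError("config needs a 'cohorts' mapping with two cohorts")
    base = path.parent

    def _resolve(p):
        p = Path(p)
        return str(p if p.is_absolute() else base / p)

    for cohort, entry in cfg["cohorts"].items():
        entry["beta"] = _resolve(entry["beta"])
        entry["samples"] = _resolve(entry["samples"])
    for key in ("manifest", "transcripts", "chromatin_states", "counts", "de_table",
                "gene_sets", "output_dir"):
        if cfg.get(key):
            cfg[key] = _resolve(cfg[key])
    cfg["_config_raw"] = raw
    return cfg


def _methylation_contrast(cfg: dict) -> Contrast:
    spec = cfg["contrasts"]["methylation"]
    return Contrast(
        name="LU_vs_" + "+".join(spec["reference"]),
        target=frozenset(spec["target"]),
        reference=frozenset(spec["reference"]),
    )


def run_pipeline(cfg: dict) -> dict:
    """Run every stage and write the result bundle under cfg['output_dir'].

    Returns a dict of in-memory stage results plus the run manifest.
    """
    outdir = Path(cfg.get("output_dir", "epimet_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    th = cfg["thresholds"]
    manifest_counts: dict[str, object] = {}

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("epimet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    results: dict[str, object] = {}
    try:
        # --- inputs --------------------------------------------------------
        probe_manifest = io_formats.read_manifest(cfg["manifest"])
        transcripts = io_formats.read_transcripts(cfg["transcripts"])
        states = io_formats.read_chromatin_bed(cfg["chromatin_states"]) if cfg.get("chromatin_states") else None
        cohort_names = list(cfg["cohorts"])
        betas, sheets = {}, {}
        for cohort, entry in cfg["cohorts"].items():
            betas[cohort] = io_formats.read_beta_matrix(entry["beta"], manifest=probe_manifest)
            sheets[cohort] = io_formats.read_sample_sheet(entry["samples"])
            io_formats.check_pairing(betas[cohort], sheets[cohort])

        # --- DMS calling per cohort ----------------------------------------
        contrast = _methylation_contrast(cfg)
        dms = {}
        for cohort in cohort_names:
            dms[cohort] = call_dms(
                betas[cohort], sheets[cohort], contrast,
                delta_threshold=th["delta_beta"], p_threshold=th["p_value"],
                use_q=th["use_q"],
            )
            io_formats.write_result_table(dms[cohort], outdir / f"dms_{cohort}.tsv", "dms")
            manifest_counts[f"dms_{cohort}"] = {
                "n_tested": dms[cohort].attrs["n_tested"],
                "n_hyper": dms[cohort].attrs["n_hyper"],
                "n_hypo": dms[cohort].attrs["n_hypo"],
            }

        # --- annotation ----------------------------------------------------
        promoters = build_promoters(transcripts)
        annotation = assign_probes(probe_manifest, promoters, states)
        write_probe_annotation(annotation, outdir / "probe_annotation.tsv")

        # --- gene classes per cohort ----------------------------------------
        calls = {}
        for cohort in cohort_names:
            counts_df = count_promoter_dms(dms[cohort], annotation)
            calls[cohort] = classify_genes(counts_df)
            io_formats.write_result_table(
                calls[cohort], outdir / f"gene_calls_{cohort}.tsv", "gene_methylation"
            )
            manifest_counts[f"gene_classes_{cohort}"] = calls[cohort].attrs["class_totals"]

        # --- cross-cohort concordance ---------------------------------------
        a, b = cohort_names[0], cohort_names[1]
        concordance = concordance_filter(calls[a], calls[b])
        concordance.to_csv(outdir / "concordance.tsv", sep="\t", index=False)
        manifest_counts["concordance"] = concordance.attrs["status_totals"]

        # --- expression ------------------------------------------------------
        if cfg.get("de_table"):
            de_raw = io_formats.read_expression_table(cfg["de_table"])
            de_source = "external"
        elif cfg.get("counts"):
            counts = pd.read_csv(cfg["counts"], sep="\t", index_col=0)
            expr_cohort = cfg.get("expression_cohort", b)
            groups = sheets[expr_cohort].set_index("sample_id")["group"]
            espec = cfg["contrasts"]["expression"]
            de_raw = standin_de_test(counts, groups, target=espec["target"],
                                     reference=espec["reference"])
            de_source = de_raw.attrs["method"]
        else:
            raise ValidationError("config needs either 'de_table' or 'counts'")
        de_filtered = filter_low_expression(de_raw, min_base_mean=th["min_base_mean"])
        expr_dirs = de_genes(de_filtered, lfc_threshold=th["lfc"], p_threshold=th["de_p"])
        de_filtered.to_csv(outdir / "de_filtered.tsv", sep="\t", index=False)
        manifest_counts["de"] = {
            "source": de_source,
            "n_genes_tested": len(de_raw),
            "n_after_base_mean_filter": len(de_filtered),
            "n_up": int((expr_dirs["expression_direction"] == "up").sum()),
            "n_down": int((expr_dirs["expression_direction"] == "down").sum()),
        }

        # --- integration -----------------------------------------------------
        integrated = integrate(concordance, expr_dirs)
        io_formats.write_result_table(integrated, outdir / "integrated.tsv", "integrated")
        manifest_counts["integrated"] = {
            "n_epigenetically_regulated": int(integrated["epigenetically_regulated"].sum())
        }

        # --- enrichments (cohort A DMS) ---------------------------------------
        chrom_enr = chromosome_enrichment(dms[a], probe_manifest)
        io_formats.write_result_table(chrom_enr, outdir / "enrichment_chromosome.tsv", "enrichment")
        for facet in ("cpg_context", "chromatin_state"):
            for direction in ("hyper", "hypo"):
                enr = context_enrichment(dms[a], annotation, facet=facet, direction=direction)
                io_formats.write_result_table(
                    enr, outdir / f"enrichment_{facet}_{direction}.tsv", "enrichment"
                )
        if cfg.get("gene_sets"):
            sets = io_formats.read_gmt(cfg["gene_sets"])
            universe = {g for hits in annotation["promoter_hits"] for g, _t in hits}
            query = set(
                integrated.loc[integrated["epigenetically_regulated"], "gene_id"]
            ) & universe
            ora_rows = ora(query, sets, universe)
            io_formats.write_result_table(ora_rows, outdir / "enrichment_gene_sets.tsv", "enrichment")
            results["ora"] = ora_rows

        # --- methylome distance trees -----------------------------------------
        trees = {}
        for cohort in cohort_names:
            k = min(int(th["top_k"]), betas[cohort].shape[0])
            probes = top_variable_sites(betas[cohort], k)
            dist = spearman_distance(betas[cohort], probes)
            tree = cluster_tree(dist, method=cfg.get("linkage", "average"))
            dist.to_csv(outdir / f"distance_{cohort}.tsv", sep="\t")
            (outdir / f"tree_{cohort}.nwk").write_text(tree.newick + "\n")
            trees[cohort] = tree

        run_manifest = {
            "package_version": __version__,
            "seed": cfg.get("seed", 0),
            "thresholds": th,
            "contrast": contrast.name,
            "cohorts": cohort_names,
            "counts": manifest_counts,
            "config": cfg.get("_config_raw"),
        }
        (outdir / "run_manifest.json").write_text(
            json.dumps(run_manifest, indent=2, sort_keys=True, default=str) + "\n"
        )
        results.update(
            dms=dms, annotation=annotation, calls=calls, concordance=concordance,
            de_table=de_filtered, expression_directions=expr_dirs,
            integrated=integrated, chromosome_enrichment=chrom_enr, trees=trees,
            run_manifest=run_manifest,
        )
        return results
    finally:
        root.removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# Fixture presets
# ---------------------------------------------------------------------------

PRESETS: dict[str, dict] = {
    "tiny": dict(
        n_probes=2000, n_genes=150,
        samples_per_group={"PT": 3, "LN": 3, "LU": 3},
        n_planted_dms_genes=20, n_isolated_planted=20,
    ),
    "default": dict(),
    "null": dict(n_planted_dms_genes=0, n_isolated_planted=0, planted_delta_beta=0.0),
}


def make_fixtures(out_dir, preset: str = "tiny", seed: int = 0) -> dict[str, str]:
    """Write a complete synthetic input bundle plus a ready pipeline config.

    Presets: 'tiny' (fast end-to-end), 'default' (the standard synthetic
    study conditions), 'null' (no planted effects).
    """
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; known: {sorted(PRESETS)}")
    out_dir = Path(out_dir)
    sim_cfg = SimulationConfig(seed=seed, **PRESETS[preset])
    result = simulate_cohorts(sim_cfg)
    paths = write_simulation(result, out_dir)

    cohort_a, cohort_b = sim_cfg.cohorts
    pipeline_cfg = {
        "seed": seed,
        "output_dir": "results",
        "cohorts": {
            cohort_a: {"beta": f"beta_{cohort_a}.tsv", "samples": f"samples_{cohort_a}.tsv"},
            cohort_b: {"beta": f"beta_{cohort_b}.tsv", "samples": f"samples_{cohort_b}.tsv"},
        },
        "manifest": "manifest.tsv",
        "transcripts": "transcripts.tsv",
        "chromatin_states": "chromatin_states.bed",
        "counts": "counts.tsv",
        "expression_cohort": cohort_b,
        "thresholds": dict(DEFAULT_THRESHOLDS),
    }
    cfg_path = out_dir / "pipeline_config.yaml"
    cfg_path.write_text(yaml.safe_dump(pipeline_cfg, sort_keys=True))
    paths["pipeline_config.yaml"] = str(cfg_path)
    return paths
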