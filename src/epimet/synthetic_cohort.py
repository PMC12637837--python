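"""Self-consistent synthetic two-cohort inputs with exported planted truth.

The generator emulates the structure of a xenograft + patient validation
study: two cohorts (default names XEN and AUR) of methylation β matrices over
a shared probe manifest, with PT/LN/LU sample groups, a transcript table with
strand-aware TSSs, a tiled chromatin-state segmentation, negative-binomial
RNA counts for the second cohort and a differential-expression table.

β-values are drawn from Beta distributions around a bimodal baseline (a low
and a high methylation mode). Planted effects shift the *mean* of the Beta
distribution for the lung-metastasis (LU) group before sampling — never by
adding a constant to drawn values — so β stays in [0, 1] without truncation
artifacts. Every planted gene receives at least two planted probes inside its
promoter window, so the downstream "≥2 promoter DMS" gene rule is satisfiable
by construction; additional isolated planted probes (outside any promoter)
exercise the rule's rejection side and carry the configurable open-sea /
heterochromatin enrichment of hypermethylated sites.

Direction mix defaults to 90% hypomethylation, mirroring the hypo-dominant
methylation loss of distant metastases; a configurable fraction of planted
genes is concordant between cohorts, and a fraction of concordant genes gets
coupled expression with direction opposing the methylation change.

Identical config + seed gives bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .gene_integration import standin_de_test
from .io_formats import BetaMatrix, ValidationError

_BACKGROUND_STATE_WEIGHTS = {
    "heterochromatin": 0.30,
    "active_transcription": 0.25,
    "other": 0.20,
    "enhancer": 0.15,
    "insulator": 0.10,
}
_PROMOTER_CONTEXT_WEIGHTS = {"island": 0.60, "shore": 0.25, "shelf": 0.10, "open_sea": 0.05}
_BACKGROUND_CONTEXT_WEIGHTS = {"open_sea": 0.55, "shelf": 0.15, "shore": 0.15, "island": 0.15}

_GENE_SPACING = 30_000
_CHROM_PAD = 50_000
_STATE_TILE = 5_000


def _default_chromosomes() -> dict[str, float]:
    return {
        "chr1": 0.20, "chr2": 0.18, "chr3": 0.16, "chr5": 0.14,
        "chr7": 0.12, "chr13": 0.10, "chrX": 0.10,
    }


def _default_samples() -> dict[str, int]:
    return {"PT": 4, "LN": 4, "LU": 4}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    Defaults are desk-scale: 20,000 probes over 1,200 genes, two cohorts of
    4 samples per site group, a 0.30 planted Δβ with a 90% hypomethylation
    direction mix, 90% cross-cohort concordance and 30% of concordant planted
    genes with coupled (anti-correlated) expression.
    """

    n_probes: int = 20_000
    n_genes: int = 1_200
    chromosomes: dict[str, float] = field(default_factory=_default_chromosomes)
    samples_per_group: dict[str, int] = field(default_factory=_default_samples)
    cohorts: tuple[str, str] = ("XEN", "AUR")
    # baseline β mixture and within-group precision
    beta_low_mean: float = 0.15
    beta_high_mean: float = 0.85
    high_mode_weight: float = 0.5
    beta_concentration: float = 50.0
    # planted methylation effects
    n_planted_dms_genes: int = 60
    probes_per_promoter: tuple[int, int] = (2, 5)
    planted_delta_beta: float = 0.30
    fraction_hypo: float = 0.90
    concordant_fraction: float = 0.90
    n_isolated_planted: int = 100
    isolated_enrichment_bias: float = 0.70
    # expression coupling
    expression_coupled_fraction: float = 0.30
    nb_mean: float = 200.0
    nb_dispersion: float = 0.1
    planted_log2fc: float = 2.0
    seed: int = 0

    def __post_init__(self):
        fracs = {
            "high_mode_weight": self.high_mode_weight,
            "fraction_hypo": self.fraction_hypo,
            "concordant_fraction": self.concordant_fraction,
            "expression_coupled_fraction": self.expression_coupled_fraction,
            "isolated_enrichment_bias": self.isolated_enrichment_bias,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_planted_dms_genes > self.n_genes:
            raise ValidationError(
                f"n_planted_dms_genes={self.n_planted_dms_genes} exceeds n_genes={self.n_genes}"
            )
        if self.n_planted_dms_genes > 0 and not 0.0 < self.planted_delta_beta < 1.0:
            raise ValidationError("planted_delta_beta must be in (0, 1) when genes are planted")
        if not 0.0 <= self.planted_delta_beta < 1.0:
            raise ValidationError("planted_delta_beta must be in [0, 1)")


@dataclass
class GroundTruth:
    """Planted truth: per-probe directions per cohort and per-gene labels."""

    probes: pd.DataFrame  # probe_id + one direction column per cohort
    genes: pd.DataFrame   # gene_id, class_<cohort>, expression_direction,
                          # concordant, epigenetically_regulated


@dataclass
class SimulationResult:
    config: SimulationConfig
    betas: dict[str, BetaMatrix]
    sheets: dict[str, pd.DataFrame]
    manifest: pd.DataFrame
    transcripts: pd.DataFrame
    states: pd.DataFrame
    counts: pd.DataFrame
    de_table: pd.DataFrame
    truth: GroundTruth


def _weighted_choice(rng: np.random.Generator, weights: dict[str, float], size: int) -> np.ndarray:
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    p = p / p.sum()
    return rng.choice(keys, size=size, p=p)


def simulate_cohorts(config: SimulationConfig) -> SimulationResult:
    """Generate the full synthetic input bundle with planted ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    cohort_a, cohort_b = cfg.cohorts

    # --- genes, transcripts, chromosome layout -----------------------------
    chrom_names = list(cfg.chromosomes)
    gene_chrom = _weighted_choice(rng, cfg.chromosomes, cfg.n_genes)
    gene_chrom.sort(kind="stable")
    per_chrom_index: dict[str, int] = {c: 0 for c in chrom_names}
    gene_rows = []
    for g in range(cfg.n_genes):
        chrom = gene_chrom[g]
        idx = per_chrom_index[chrom]
        per_chrom_index[chrom] += 1
        tss = 20_000 + idx * _GENE_SPACING
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "protein_coding" if rng.random() < 0.9 else "lncRNA"
        gene_rows.append((f"G{g:05d}", chrom, int(tss), strand, biotype))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chromosome", "tss", "strand", "biotype"])
    chrom_len = {
        c: 20_000 + per_chrom_index[c] * _GENE_SPACING + _CHROM_PAD for c in chrom_names
    }

    tx_rows = []
    tx_counter = 0
    for row in genes.itertuples(index=False):
        n_tx = int(rng.integers(1, 4))
        for t in range(n_tx):
            offset = 0 if t == 0 else int(rng.integers(-400, 401))
            tx_rows.append(
                (row.gene_id, f"T{tx_counter:06d}", row.chromosome, row.strand,
                 max(row.tss + offset, 2_100), row.biotype)
            )
            tx_counter += 1
    transcripts = pd.DataFrame(
        tx_rows, columns=["gene_id", "transcript_id", "chromosome", "strand", "tss", "biotype"]
    )

    # --- planted genes and directions --------------------------------------
    coding = genes[genes["biotype"] == "protein_coding"]["gene_id"].to_numpy()
    if cfg.n_planted_dms_genes > coding.size:
        raise ValidationError(
            f"n_planted_dms_genes={cfg.n_planted_dms_genes} exceeds "
            f"{coding.size} protein-coding genes"
        )
    planted_genes = rng.choice(coding, size=cfg.n_planted_dms_genes, replace=False)
    planted_genes = np.sort(planted_genes)
    direction_a = np.where(
        rng.random(planted_genes.size) < cfg.fraction_hypo, "hypo", "hyper"
    )
    concordant = rng.random(planted_genes.size) < cfg.concordant_fraction
    direction_b = np.where(
        concordant, direction_a, np.where(direction_a == "hypo", "hyper", "hypo")
    )
    gene_dir_a = dict(zip(planted_genes, direction_a))
    gene_dir_b = dict(zip(planted_genes, direction_b))
    gene_concordant = dict(zip(planted_genes, concordant))

    # --- chromatin-state segmentation (non-overlapping tiles) --------------
    state_rows = []
    tss_by_chrom = genes.groupby("chromosome")["tss"].apply(list).to_dict()
    for chrom in chrom_names:
        length = chrom_len[chrom]
        n_tiles = length // _STATE_TILE + 1
        tile_states = _weighted_choice(rng, _BACKGROUND_STATE_WEIGHTS, n_tiles)
        promoter_tiles = {int(t) // _STATE_TILE for t in tss_by_chrom.get(chrom, [])}
        for i in range(n_tiles):
            state = "promoter" if i in promoter_tiles else tile_states[i]
            state_rows.append((chrom, i * _STATE_TILE + 1, (i + 1) * _STATE_TILE, state))
    states = pd.DataFrame(state_rows, columns=["chromosome", "start", "end", "state"])

    # --- probes: promoter probes per gene, then background, then isolated --
    probe_rows = []  # (probe_id, chromosome, position, cpg_context)
    probe_dir_a: dict[str, str] = {}
    probe_dir_b: dict[str, str] = {}
    probe_counter = 0

    def _new_probe(chrom: str, pos: int, context: str) -> str:
        nonlocal probe_counter
        pid = f"cg{probe_counter:08d}"
        probe_counter += 1
        probe_rows.append((pid, chrom, int(pos), context))
        return pid

    lo, hi = cfg.probes_per_promoter
    for row in genes.itertuples(index=False):
        is_planted = row.gene_id in gene_dir_a
        if row.biotype != "protein_coding" and not is_planted:
            # a few promoter-like probes near non-coding genes still exist
            if rng.random() < 0.5:
                continue
        n_pp = int(rng.integers(lo, hi + 1))
        if row.strand == "+":
            w0, w1 = row.tss - 2000, row.tss - 1
        else:
            w0, w1 = row.tss + 1, row.tss + 2000
        positions = rng.choice(np.arange(w0, w1 + 1), size=n_pp, replace=False)
        contexts = _weighted_choice(rng, _PROMOTER_CONTEXT_WEIGHTS, n_pp)
        for pos, ctx in zip(np.sort(positions), contexts):
            pid = _new_probe(row.chromosome, pos, ctx)
            if is_planted:
                probe_dir_a[pid] = gene_dir_a[row.gene_id]
                probe_dir_b[pid] = gene_dir_b[row.gene_id]

    n_so_far = probe_counter
    n_background = cfg.n_probes - n_so_far - cfg.n_isolated_planted
    if n_background < 0:
        raise ValidationError(
            f"n_probes={cfg.n_probes} too small for {n_so_far} promoter probes "
            f"+ {cfg.n_isolated_planted} isolated planted probes"
        )
    bg_chrom = _weighted_choice(rng, cfg.chromosomes, n_background)
    bg_context = _weighted_choice(rng, _BACKGROUND_CONTEXT_WEIGHTS, n_background)
    for chrom, ctx in zip(bg_chrom, bg_context):
        pos = int(rng.integers(1, chrom_len[chrom] + 1))
        _new_probe(chrom, pos, ctx)

    # isolated planted probes: not tied to genes; hypermethylated ones are
    # biased toward open-sea context and heterochromatin tiles
    het_tiles = {
        chrom: states[(states["chromosome"] == chrom) & (states["state"] == "heterochromatin")]
        for chrom in chrom_names
    }
    iso_dir = np.where(
        rng.random(cfg.n_isolated_planted) < cfg.fraction_hypo, "hypo", "hyper"
    )
    for d in iso_dir:
        chrom = _weighted_choice(rng, cfg.chromosomes, 1)[0]
        biased = d == "hyper" and rng.random() < cfg.isolated_enrichment_bias
        tiles = het_tiles[chrom]
        if biased and len(tiles):
            tile = tiles.iloc[int(rng.integers(0, len(tiles)))]
            pos = int(rng.integers(tile["start"], tile["end"] + 1))
            ctx = "open_sea"
        else:
            pos = int(rng.integers(1, chrom_len[chrom] + 1))
            ctx = _weighted_choice(rng, _BACKGROUND_CONTEXT_WEIGHTS, 1)[0]
        pid = _new_probe(chrom, pos, ctx)
        probe_dir_a[pid] = d
        probe_dir_b[pid] = d

    manifest = pd.DataFrame(probe_rows, columns=["probe_id", "chromosome", "position", "cpg_context"])
    manifest = io_formats.validate_manifest(manifest, chromosomes=chrom_names)
    n_probes = len(manifest)

    # --- baseline β means ----------------------------------------------------
    probe_ids = manifest["probe_id"].to_numpy()
    high_mode = rng.random(n_probes) < cfg.high_mode_weight
    m0 = np.where(
        high_mode,
        rng.normal(cfg.beta_high_mean, 0.06, n_probes),
        rng.normal(cfg.beta_low_mean, 0.06, n_probes),
    )
    dir_a = np.array([probe_dir_a.get(p, "none") for p in probe_ids])
    dir_b = np.array([probe_dir_b.get(p, "none") for p in probe_ids])
    discordant_probe = dir_a != dir_b
    # planted baselines must leave room for the shift
    m0 = np.where((dir_a == "hypo") & ~discordant_probe, rng.normal(cfg.beta_high_mean, 0.04, n_probes), m0)
    m0 = np.where((dir_a == "hyper") & ~discordant_probe, rng.normal(cfg.beta_low_mean, 0.04, n_probes), m0)
    m0 = np.where(discordant_probe, rng.normal(0.5, 0.03, n_probes), m0)
    m0 = np.clip(m0, 0.03, 0.97)

    def _shifted_mean(direction: np.ndarray) -> np.ndarray:
        shift = np.where(direction == "hypo", -cfg.planted_delta_beta,
                         np.where(direction == "hyper", cfg.planted_delta_beta, 0.0))
        return np.clip(m0 + shift, 0.02, 0.98)

    # --- draw β per cohort ---------------------------------------------------
    betas: dict[str, BetaMatrix] = {}
    sheets: dict[str, pd.DataFrame] = {}
    lu_means = {cohort_a: _shifted_mean(dir_a), cohort_b: _shifted_mean(dir_b)}
    conc = cfg.beta_concentration
    for cohort in cfg.cohorts:
        cols = {}
        sheet_rows = []
        for group, n_samples in cfg.samples_per_group.items():
            mean = lu_means[cohort] if group == "LU" else m0
            for s in range(n_samples):
                sid = f"{cohort}_{group}_{s + 1}"
                cols[sid] = rng.beta(mean * conc, (1.0 - mean) * conc)
                sheet_rows.append((sid, group, cohort))
        values = pd.DataFrame(cols, index=probe_ids)
        values.index.name = "probe_id"
        betas[cohort] = BetaMatrix(values)
        sheets[cohort] = io_formats.validate_sample_sheet(
            pd.DataFrame(sheet_rows, columns=["sample_id", "group", "cohort"])
        )

    # --- expression: NB counts for the second cohort -------------------------
    concordant_planted = planted_genes[concordant]
    n_coupled = int(round(cfg.expression_coupled_fraction * concordant_planted.size))
    coupled_genes = set(
        rng.choice(concordant_planted, size=n_coupled, replace=False)
    ) if n_coupled else set()

    expr_sheet = sheets[cohort_b]
    sample_ids = expr_sheet["sample_id"].to_numpy()
    sample_groups = expr_sheet.set_index("sample_id")["group"]
    gene_ids = genes["gene_id"].to_numpy()
    base_mu = rng.lognormal(np.log(cfg.nb_mean), 0.6, gene_ids.size)
    lfc = np.zeros(gene_ids.size)
    expr_direction = np.full(gene_ids.size, "none", dtype=object)
    for i, g in enumerate(gene_ids):
        if g in coupled_genes:
            # expression opposes methylation: hypo -> up, hyper -> down
            sign = 1.0 if gene_dir_b[g] == "hypo" else -1.0
            lfc[i] = sign * cfg.planted_log2fc
            expr_direction[i] = "up" if sign > 0 else "down"
    mu = np.tile(base_mu[:, None], (1, sample_ids.size))
    is_lu = (sample_groups.loc[sample_ids] == "LU").to_numpy()
    mu[:, is_lu] = mu[:, is_lu] * (2.0 ** lfc)[:, None]
    r = 1.0 / cfg.nb_dispersion
    counts_arr = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(counts_arr, index=gene_ids, columns=sample_ids)
    counts.index.name = "gene_id"

    de_table = standin_de_test(counts, sample_groups, target="LU", reference="PT")

    # --- ground truth ---------------------------------------------------------
    probes_truth = pd.DataFrame(
        {"probe_id": probe_ids, cohort_a: dir_a, cohort_b: dir_b}
    )
    gene_truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            f"class_{cohort_a}": [gene_dir_a.get(g, "none") for g in gene_ids],
            f"class_{cohort_b}": [gene_dir_b.get(g, "none") for g in gene_ids],
            "expression_direction": expr_direction,
            "concordant": [bool(gene_concordant.get(g, False)) for g in gene_ids],
            "epigenetically_regulated": [
                g in coupled_genes and gene_concordant.get(g, False) for g in gene_ids
            ],
        }
    )
    truth = GroundTruth(probes=probes_truth, genes=gene_truth)

    return SimulationResult(
        config=cfg,
        betas=betas,
        sheets=sheets,
        manifest=manifest,
        transcripts=io_formats.validate_transcripts(transcripts),
        states=states,
        counts=counts,
        de_table=de_table,
        truth=truth,
    )


def truth_confusion(
    dms: pd.DataFrame, truth: GroundTruth, cohort: str
) -> dict[str, int]:
    """Probe-level confusion counts of a DMS table against the planted truth.

    The universe is the truth's probe set; probes skipped by the caller count
    as not called. TP + FP + FN + TN equals the probe universe size.
    """
    if cohort not in truth.probes.columns:
        raise ValidationError(f"cohort {cohort!r} not in truth table")
    extra = set(dms["probe_id"]) - set(truth.probes["probe_id"])
    if extra:
        raise ValidationError(
            f"DMS probes outside the truth universe (e.g. {sorted(extra)[:5]})"
        )
    planted = truth.probes.set_index("probe_id")[cohort] != "none"
    called = dms.set_index("probe_id")["is_dms"].reindex(planted.index).fillna(False).astype(bool)
    tp = int((planted & called).sum())
    fp = int((~planted & called).sum())
    fn = int((planted & ~called).sum())
    tn = int((~planted & ~called).sum())
    return {"TP": tp, "FP": fp, "FN": fn, "TN": tn}


def gene_confusion(calls: pd.DataFrame, truth: GroundTruth, cohort: str) -> dict[str, int]:
    """Gene-level confusion: called class != none vs planted class != none."""
    col = f"class_{cohort}"
    if col not in truth.genes.columns:
        raise ValidationError(f"cohort {cohort!r} not in gene truth table")
    planted = truth.genes.set_index("gene_id")[col] != "none"
    called_classes = calls.set_index("gene_id")["meth_class"].reindex(planted.index)
    called = called_classes.notna() & (called_classes != "none")
    tp = int((planted & called).sum())
    fp = int((~planted & called).sum())
    fn = int((planted & ~called).sum())
    tn = int((~planted & ~called).sum())
    return {"TP": tp, "FP": fp, "FN": fn, "TN": tn}


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def write_simulation(result: SimulationResult, outdir) -> dict[str, str]:
    """Write every pipeline input plus truth tables and a metadata record.

    Returns a mapping of logical names to written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _save(name: str, fn) -> None:
        path = outdir / name
        fn(path)
        paths[name] = str(path)

    for cohort in result.config.cohorts:
        _save(f"beta_{cohort}.tsv", lambda p, c=cohort: io_formats.write_beta_matrix(result.betas[c], p))
        _save(f"samples_{cohort}.tsv", lambda p, c=cohort: result.sheets[c].to_csv(p, sep="\t", index=False))
    _save("manifest.tsv", lambda p: result.manifest.to_csv(p, sep="\t", index=False))
    _save("transcripts.tsv", lambda p: result.transcripts.to_csv(p, sep="\t", index=False))
    _save("chromatin_states.bed", lambda p: io_formats.write_chromatin_bed(result.states, p))
    _save("counts.tsv", lambda p: result.counts.to_csv(p, sep="\t"))
    _save("de_table.tsv", lambda p: result.de_table.to_csv(p, sep="\t", index=False))
    _save("truth_probes.tsv", lambda p: result.truth.probes.to_csv(p, sep="\t", index=False))
    _save("truth_genes.tsv", lambda p: result.truth.genes.to_csv(p, sep="\t", index=False))

    meta = dataclasses.asdict(result.config)
    meta["probes_per_promoter"] = list(meta["probes_per_promoter"])
    meta["cohorts"] = list(meta["cohorts"])
    meta_path = outdir / "simulation_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    paths["simulation_metadata.json"] = str(meta_path)
    return paths
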