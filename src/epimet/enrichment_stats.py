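"""2×2 and over-representation enrichment statistics.

Every enrichment in the pipeline reduces to a 2×2 table against the probe (or
gene) universe: per-chromosome DMS enrichment against array probe density,
CpG-context and chromatin-state enrichment per methylation direction, and
hypergeometric over-representation of gene sets. Odds ratios are the sample
cross-product (a·d)/(b·c) with Woolf (log-OR) 95% confidence intervals and
Haldane–Anscombe +0.5 correction at zero cells; p-values use Fisher's exact
test with the two-sided "probability ≤ observed" convention. Each enrichment
family (chromosomes, contexts, states, gene sets) is Benjamini–Hochberg
corrected separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .dms_calling import bh_adjust
from .io_formats import GeneSetCollection, ValidationError


def _check_cells(a: int, b: int, c: int, d: int) -> None:
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValidationError(f"2x2 cells must be nonnegative integers, got {(a, b, c, d)}")


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio (a·d)/(b·c); ∞ or 0 at zero cells, NaN if both."""
    _check_cells(a, b, c, d)
    num, den = a * d, b * c
    if den == 0:
        return np.nan if num == 0 else np.inf
    return num / den


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for a 2×2 table.

    p sums the probabilities of all tables with the observed margins whose
    hypergeometric probability is at most that of the observed table.
    """
    _check_cells(a, b, c, d)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds_ratio(a, b, c, d), float(p)


def or_confidence_interval(
    a: int, b: int, c: int, d: int, level: float = 0.95
) -> tuple[float, float]:
    """Woolf log-OR confidence interval, Haldane–Anscombe corrected at zeros."""
    _check_cells(a, b, c, d)
    if not 0 < level < 1:
        raise ValidationError("confidence level must be in (0, 1)")
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    log_or = np.log((a_ * d_) / (b_ * c_))
    se = np.sqrt((1 / cells).sum())
    z = stats.norm.ppf(0.5 + level / 2)
    return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def _enrichment_rows(tables: list[tuple[str, int, int, int, int]]) -> pd.DataFrame:
    rows = []
    for category, a, b, c, d in tables:
        or_, p = fisher_2x2(a, b, c, d)
        lo, hi = or_confidence_interval(a, b, c, d)
        rows.append(
            {
                "category": category, "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": or_, "ci_low": lo, "ci_high": hi, "p_value": p,
                "degenerate": min(a, b, c, d) == 0,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    cols = ["category", "a", "b", "c", "d", "odds_ratio", "ci_low", "ci_high",
            "p_value", "q_value", "degenerate"]
    return out[cols] if len(out) else pd.DataFrame(columns=cols)


def chromosome_enrichment(dms: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome DMS enrichment against array probe density.

    For each chromosome: a = DMS on it, b = DMS elsewhere, c = non-DMS on it,
    d = non-DMS elsewhere. The expected DMS count under the probe-density
    null (total DMS × chromosome probe share) is reported alongside the
    Fisher OR/CI/p and BH q across chromosomes.
    """
    probe_chrom = manifest.set_index("probe_id")["chromosome"]
    missing = set(dms["probe_id"]) - set(probe_chrom.index)
    if missing:
        raise ValidationError(f"DMS probes missing from manifest (e.g. {sorted(missing)[:5]})")
    is_dms = dms.set_index("probe_id")["is_dms"]
    universe = probe_chrom.to_frame()
    universe["is_dms"] = is_dms.reindex(universe.index).fillna(False).astype(bool)
    total_dms = int(universe["is_dms"].sum())
    total = len(universe)
    tables, expected = [], []
    for chrom, grp in universe.groupby("chromosome", sort=True):
        a = int(grp["is_dms"].sum())
        c = len(grp) - a
        b = total_dms - a
        d = total - total_dms - c
        tables.append((chrom, a, b, c, d))
        expected.append(total_dms * len(grp) / total)
    out = _enrichment_rows(tables)
    out["expected_dms"] = expected
    return out


def context_enrichment(
    dms: pd.DataFrame,
    annotation: pd.DataFrame,
    facet: str = "cpg_context",
    direction: str = "hyper",
) -> pd.DataFrame:
    """Enrichment of direction-specific DMS across CpG contexts or chromatin
    states, against all non-DMS probes (forest-plot-ready).

    The universe per table is direction-specific DMS plus non-DMS probes;
    DMS of the opposite direction are excluded. With zero DMS in the
    requested direction every row is degenerate but still emitted.
    """
    if facet not in ("cpg_context", "chromatin_state"):
        raise ValidationError("facet must be 'cpg_context' or 'chromatin_state'")
    if direction not in ("hyper", "hypo"):
        raise ValidationError("direction must be 'hyper' or 'hypo'")
    ann = annotation.set_index("probe_id")[facet]
    missing = set(dms["probe_id"]) - set(ann.index)
    if missing:
        raise ValidationError(f"DMS probes missing from annotation (e.g. {sorted(missing)[:5]})")
    tab = dms.set_index("probe_id")[["direction"]].join(ann)
    sel = tab[(tab["direction"] == direction) | (tab["direction"] == "none")]
    is_dir = (sel["direction"] == direction).to_numpy()
    n_dir = int(is_dir.sum())
    n_non = len(sel) - n_dir
    tables = []
    for cat in sorted(sel[facet].unique()):
        in_cat = (sel[facet] == cat).to_numpy()
        a = int((in_cat & is_dir).sum())
        c = int(in_cat.sum()) - a
        tables.append((cat, a, n_dir - a, c, n_non - c))
    return _enrichment_rows(tables)


def ora(
    query: set[str] | list[str],
    sets: GeneSetCollection,
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each gene set.

    p = P(X ≥ k) with universe size N, set size K (after intersecting the set
    with the universe), query size n, overlap k; BH q across sets. Rows are
    emitted even at k = 0.
    """
    universe = set(universe)
    query = set(query)
    if not query <= universe:
        raise ValidationError("ora: query genes must be a subset of the universe")
    n = len(query)
    N = len(universe)
    tables, pvals, names = [], [], []
    for name in sets:
        members = sets[name] & universe
        K = len(members)
        k = len(members & query)
        pvals.append(float(stats.hypergeom.sf(k - 1, N, K, n)))
        names.append(name)
        tables.append((name, k, n - k, K - k, N - K - n + k))
    rows = []
    for (name, a, b, c, d), p in zip(tables, pvals):
        lo, hi = or_confidence_interval(a, b, c, d)
        rows.append(
            {
                "category": name, "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": odds_ratio(a, b, c, d), "ci_low": lo, "ci_high": hi,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out
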