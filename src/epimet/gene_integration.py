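"""Gene-level integration of promoter methylation and expression.

Genes with at least two promoter DMS are classified as hyper-, hypo- or
mixed-methylated; classes are compared across two cohorts (discordant genes
dropped); the concordant set is intersected with direction-consistent
expression changes — promoter hypomethylation coupled with upregulation, or
hypermethylation coupled with downregulation — to yield the epigenetically
regulated gene set.

The expression-side utilities (median-of-ratios size factors, base-mean
filter, log2 pseudocount-1 transform, the differential-expression gene rule,
and a clearly labelled stand-in location test for synthetic end-to-end runs)
also live here.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dms_calling import bh_adjust
from .io_formats import ValidationError, validate_expression_table

logger = logging.getLogger(__name__)

MIN_PROMOTER_DMS = 2
METH_CLASSES = ("hyper", "hypo", "mixed", "none")


def classify_genes(counts: pd.DataFrame) -> pd.DataFrame:
    """Assign a promoter-methylation class per gene from DMS counts.

    ``none`` when fewer than two promoter DMS in total; otherwise ``hyper``
    (all hyper), ``hypo`` (all hypo) or ``mixed`` (both directions present).
    """
    n_hyper = counts["n_hyper"].to_numpy()
    n_hypo = counts["n_hypo"].to_numpy()
    total = n_hyper + n_hypo
    meth_class = np.where(
        total < MIN_PROMOTER_DMS,
        "none",
        np.where(n_hypo == 0, "hyper", np.where(n_hyper == 0, "hypo", "mixed")),
    )
    out = counts[["gene_id", "n_hyper", "n_hypo"]].copy()
    out["meth_class"] = meth_class
    totals = out["meth_class"].value_counts().to_dict()
    out.attrs["class_totals"] = totals
    logger.info("classify_genes: %s", totals)
    return out


def concordance_filter(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> pd.DataFrame:
    """Partition classified genes of two cohorts by cross-cohort agreement.

    A gene classified (class != none) in both cohorts is concordant iff the
    class labels are identical (mixed must match mixed); discordant genes are
    flagged for removal; genes classified in one cohort only are reported as
    unshared. Returns (gene_id, class_a, class_b, status).
    """
    a = calls_a.loc[calls_a["meth_class"] != "none", ["gene_id", "meth_class"]]
    b = calls_b.loc[calls_b["meth_class"] != "none", ["gene_id", "meth_class"]]
    merged = a.merge(b, on="gene_id", how="outer", suffixes=("_a", "_b"))
    merged = merged.rename(columns={"meth_class_a": "class_a", "meth_class_b": "class_b"})
    both = merged["class_a"].notna() & merged["class_b"].notna()
    merged["status"] = np.where(
        ~both,
        "unshared",
        np.where(merged["class_a"] == merged["class_b"], "concordant", "discordant"),
    )
    merged = merged.sort_values("gene_id").reset_index(drop=True)
    counts = merged["status"].value_counts().to_dict()
    merged.attrs["status_totals"] = counts
    logger.info("concordance_filter: %s", counts)
    return merged


# ---------------------------------------------------------------------------
# Expression-side utilities
# ---------------------------------------------------------------------------


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors (genes × samples counts).

    The reference is the per-gene geometric mean across samples; genes with
    any zero count are excluded from the reference; each sample's factor is
    the median over remaining genes of count/reference.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError("size_factors: counts must be nonnegative")
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise ValidationError("size_factors: no gene with all-positive counts")
    pos = arr[all_pos]
    log_gm = np.log(pos).mean(axis=1, keepdims=True)
    ratios = pos / np.exp(log_gm)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def log_norm(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1), the pseudocount-1 transform."""
    if (factors <= 0).any():
        raise ValidationError("log_norm: size factors must be positive")
    return np.log2(counts.div(factors, axis=1) + 1.0)


def filter_low_expression(de: pd.DataFrame, min_base_mean: float = 20.0) -> pd.DataFrame:
    """Drop genes with base mean of *min_base_mean* reads or fewer (strict >)."""
    kept = de[de["base_mean"] > min_base_mean].reset_index(drop=True)
    logger.info("filter_low_expression: kept %d / %d genes", len(kept), len(de))
    return kept


def de_genes(
    de: pd.DataFrame, lfc_threshold: float = 1.0, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Assign expression direction per gene: up iff log2FC > threshold and
    p < cut-off, down iff log2FC < -threshold and p < cut-off, else none.
    All inequalities strict."""
    up = (de["log2fc"] > lfc_threshold) & (de["p_value"] < p_threshold)
    down = (de["log2fc"] < -lfc_threshold) & (de["p_value"] < p_threshold)
    out = de[["gene_id"]].copy()
    out["expression_direction"] = np.where(up, "up", np.where(down, "down", "none"))
    return out


def standin_de_test(
    counts: pd.DataFrame,
    groups: pd.Series,
    target: str,
    reference: str | Sequence[str],
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Simple location-test differential expression on log-normalised counts.

    This is a stand-in for an external differential-expression fit so that
    synthetic end-to-end runs need no external fitter: per gene, base_mean is
    the mean of size-factor-normalised counts over all samples, log2fc the
    difference of group means of log2(count/factor + 1), and p a two-sided
    Welch (unequal-variance) t-test on those values. Output schema matches an
    expression result table; the method is recorded in ``attrs['method']``.
    """
    reference = [reference] if isinstance(reference, str) else list(reference)
    groups = groups.reindex(counts.columns)
    tgt_ids = groups.index[groups == target].tolist()
    ref_ids = groups.index[groups.isin(reference)].tolist()
    if len(tgt_ids) < 2 or len(ref_ids) < 2:
        raise ValidationError("standin_de_test: each group needs >= 2 samples")
    if factors is None:
        factors = size_factors(counts)
    norm = counts.div(factors, axis=1)
    ln = log_norm(counts, factors)
    t = ln[tgt_ids].to_numpy()
    r = ln[ref_ids].to_numpy()
    lfc = t.mean(axis=1) - r.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(t, r, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # constant genes: no evidence
    out = pd.DataFrame(
        {
            "gene_id": counts.index,
            "base_mean": norm.to_numpy().mean(axis=1),
            "log2fc": lfc,
            "p_value": p,
        }
    ).reset_index(drop=True)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out.attrs["method"] = "standin_welch_on_log_norm"
    return validate_expression_table(out)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def integrate(concordance: pd.DataFrame, expression: pd.DataFrame) -> pd.DataFrame:
    """Intersect concordant methylation classes with expression directions.

    A gene is epigenetically regulated iff it is concordant across cohorts
    and its promoter methylation opposes its expression change (hypo with up,
    or hyper with down). Mixed-class genes are never flagged; discordant and
    unshared genes are retained in the table with the flag False.
    """
    expr = expression.set_index("gene_id")["expression_direction"]
    out = concordance.copy()
    out["expression_direction"] = (
        out["gene_id"].map(expr).fillna("none")
    )
    concordant = out["status"] == "concordant"
    out["concordant"] = concordant
    flagged = concordant & (
        ((out["class_a"] == "hypo") & (out["expression_direction"] == "up"))
        | ((out["class_a"] == "hyper") & (out["expression_direction"] == "down"))
    )
    out["epigenetically_regulated"] = flagged
    logger.info("integrate: %d epigenetically regulated genes", int(flagged.sum()))
    return out
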