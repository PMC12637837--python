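"""Differential methylation site (DMS) calling.

A CpG is a DMS for a contrast (e.g., lung metastases vs combined primary
tumors and lymph-node metastases) when the absolute difference of group mean
β exceeds a threshold (default 0.15) and a two-sided Wilcoxon rank-sum test
falls below a p-value cut-off (default 0.05; 0.1 for small pairwise runs).
Benjamini–Hochberg q-values are always reported and may optionally replace
the raw p in the significance rule.

The rank-sum p-value is exact (full enumeration of the Mann–Whitney U null
distribution) whenever the data are tie-free, the smaller group has at most
8 samples and the U distribution is small enough to tabulate; otherwise a
normal approximation with midranks, tie variance correction and continuity
correction is used. Threshold comparisons are strict: |Δβ| must exceed the
threshold and p must be below the cut-off; boundary values fail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import BetaMatrix, ValidationError

logger = logging.getLogger(__name__)

#: Exact enumeration is used when the smaller group has at most this many
#: usable values (and the data are tie-free).
EXACT_MAX_MIN_N = 8

#: Guard on the size of the tabulated U distribution (n1*n2); beyond this the
#: normal approximation is used even if min(n) <= EXACT_MAX_MIN_N.
EXACT_MAX_PRODUCT = 10_000


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison defined on sample-sheet group labels."""

    name: str
    reference: frozenset = field(default_factory=frozenset)
    target: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        ref = frozenset(self.reference)
        tgt = frozenset(self.target)
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "target", tgt)
        if ref & tgt:
            raise ValidationError(f"contrast {self.name!r}: reference and target overlap")
        if not ref or not tgt:
            raise ValidationError(f"contrast {self.name!r}: both sides must be non-empty")


#: The contrast used throughout: lung metastases against pooled primary
#: tumors and lymph-node metastases.
LU_VS_PT_LN = Contrast("LU_vs_PT+LN", reference=frozenset({"PT", "LN"}), target=frozenset({"LU"}))


# ---------------------------------------------------------------------------
# Exact Mann-Whitney U null distribution
# ---------------------------------------------------------------------------


@lru_cache(maxsize=128)
def _u_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank arrangements giving each U value, for group sizes n1, n2.

    Uses the recurrence f(i, j, u) = f(i-1, j, u-j) + f(i, j-1, u) over the
    number of arrangements of i target and j reference ranks.
    """
    # row[j] is the array over u for (i, j); build up i = 0..n1
    rows = [np.array([1.0]) for _ in range(n2 + 1)]  # i = 0: f = 1 at u = 0
    for i in range(1, n1 + 1):
        new_rows = [np.array([1.0])]  # j = 0
        for j in range(1, n2 + 1):
            size = i * j + 1
            arr = np.zeros(size)
            prev_i = rows[j]  # f(i-1, j), length (i-1)*j + 1
            arr[j : j + prev_i.size] += prev_i
            prev_j = new_rows[j - 1]  # f(i, j-1), length i*(j-1) + 1
            arr[: prev_j.size] += prev_j
            new_rows.append(arr)
        rows = new_rows
    return rows[n2]


@lru_cache(maxsize=128)
def _exact_p_of_u(n1: int, n2: int) -> np.ndarray:
    """Two-sided exact p for every U value: total probability of arrangements
    at least as extreme (folded about the centre nm/2)."""
    counts = _u_counts(n1, n2)
    total = comb(n1 + n2, n1)
    nm = n1 * n2
    folded = np.minimum(np.arange(nm + 1), nm - np.arange(nm + 1))
    p = np.empty(nm + 1)
    for u in range(nm + 1):
        p[u] = counts[folded <= folded[u]].sum() / total
    return np.minimum(p, 1.0)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mann-Whitney U of x vs y (midranks) and the combined rank vector."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[: x.size].sum()
    u = r1 - x.size * (x.size + 1) / 2.0
    return u, ranks


def _approx_p(u: float, n1: int, n2: int, combined: np.ndarray) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, t = np.unique(combined, return_counts=True)
    tie_term = (t**3 - t).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0  # all values identical
    z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def rank_sum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value for two samples.

    Exact by full enumeration when tie-free and the smaller sample has at
    most :data:`EXACT_MAX_MIN_N` values; otherwise the documented normal
    approximation. Missing values must be removed by the caller.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank_sum_p: both samples must be non-empty")
    u, _ = _u_statistic(x, y)
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    n1, n2 = x.size, y.size
    if (not has_ties and min(n1, n2) <= EXACT_MAX_MIN_N
            and n1 * n2 <= EXACT_MAX_PRODUCT):
        return float(_exact_p_of_u(n1, n2)[int(round(u))])
    return _approx_p(u, n1, n2, combined)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DMS calling
# ---------------------------------------------------------------------------


def _contrast_samples(sheet: pd.DataFrame, contrast: Contrast) -> tuple[list[str], list[str]]:
    ref = sheet.loc[sheet["group"].isin(contrast.reference), "sample_id"].tolist()
    tgt = sheet.loc[sheet["group"].isin(contrast.target), "sample_id"].tolist()
    if len(ref) < 2 or len(tgt) < 2:
        raise ValidationError(
            f"contrast {contrast.name!r}: each side needs >= 2 samples "
            f"(got {len(ref)} reference, {len(tgt)} target)"
        )
    return ref, tgt


def call_dms(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    contrast: Contrast = LU_VS_PT_LN,
    delta_threshold: float = 0.15,
    p_threshold: float = 0.05,
    use_q: bool = False,
) -> pd.DataFrame:
    """Call differential methylation per probe for one group contrast.

    Returns one row per tested probe with Δβ (target minus reference group
    mean), two-sided rank-sum p, BH q, direction ∈ {hyper, hypo, none} and
    the significance flag. Probes where either group has fewer than two
    usable (non-missing) values are skipped and counted in the log, never
    raised. Summary counts are attached in ``result.attrs``.
    """
    if not 0 < delta_threshold < 1:
        raise ValidationError("delta_threshold must be in (0, 1)")
    missing_groups = (contrast.reference | contrast.target) - set(sheet["group"])
    if missing_groups:
        raise ValidationError(
            f"contrast groups absent from sample sheet: {sorted(missing_groups)}"
        )
    ref_ids, tgt_ids = _contrast_samples(sheet, contrast)
    for s in ref_ids + tgt_ids:
        if s not in beta.values.columns:
            raise ValidationError(f"contrast sample {s!r} absent from beta matrix")

    ref = beta.values[ref_ids].to_numpy()
    tgt = beta.values[tgt_ids].to_numpy()
    n_ref_ok = (~np.isnan(ref)).sum(axis=1)
    n_tgt_ok = (~np.isnan(tgt)).sum(axis=1)
    usable = (n_ref_ok >= 2) & (n_tgt_ok >= 2)
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info("call_dms: skipped %d probes with <2 usable values in a group", n_skipped)

    probe_ids = np.asarray(beta.probe_ids)[usable]
    ref = ref[usable]
    tgt = tgt[usable]
    mean_ref = np.nanmean(ref, axis=1)
    mean_tgt = np.nanmean(tgt, axis=1)
    delta = mean_tgt - mean_ref
    p = _vectorized_rank_sum(tgt, ref)
    q = bh_adjust(p) if p.size else np.array([])

    stat = q if use_q else p
    is_dms = (np.abs(delta) > delta_threshold) & (stat < p_threshold)
    direction = np.where(is_dms, np.where(delta > 0, "hyper", "hypo"), "none")

    out = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "mean_beta_reference": mean_ref,
            "mean_beta_target": mean_tgt,
            "delta_beta": delta,
            "p_value": p,
            "q_value": q,
            "direction": direction,
            "is_dms": is_dms,
        }
    )
    n_hyper = int((direction == "hyper").sum())
    n_hypo = int((direction == "hypo").sum())
    out.attrs.update(
        contrast=contrast.name,
        n_tested=len(out),
        n_skipped=n_skipped,
        n_hyper=n_hyper,
        n_hypo=n_hypo,
        delta_threshold=delta_threshold,
        p_threshold=p_threshold,
        use_q=use_q,
    )
    logger.info(
        "call_dms[%s]: %d tested, %d hyper, %d hypo", contrast.name, len(out), n_hyper, n_hypo
    )
    return out


def _vectorized_rank_sum(tgt: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p for target vs reference blocks.

    Rows without missing values share group sizes, so the exact U null
    distribution is tabulated once; rows with NaN or ties fall back to the
    scalar path / normal approximation.
    """
    n_rows = tgt.shape[0]
    p = np.empty(n_rows)
    data = np.concatenate([tgt, ref], axis=1)
    complete = ~np.isnan(data).any(axis=1)

    if complete.any():
        block = data[complete]
        n1, n2 = tgt.shape[1], ref.shape[1]
        ranks = stats.rankdata(block, axis=1)
        r1 = ranks[:, :n1].sum(axis=1)
        u = r1 - n1 * (n1 + 1) / 2.0
        srt = np.sort(block, axis=1)
        tied = (np.diff(srt, axis=1) == 0).any(axis=1)
        p_block = np.empty(block.shape[0])
        exact_ok = min(n1, n2) <= EXACT_MAX_MIN_N and n1 * n2 <= EXACT_MAX_PRODUCT
        if exact_ok:
            table = _exact_p_of_u(n1, n2)
            idx = np.rint(u[~tied]).astype(int)
            p_block[~tied] = table[idx]
        else:
            for i in np.flatnonzero(~tied):
                p_block[i] = _approx_p(u[i], n1, n2, block[i])
        for i in np.flatnonzero(tied):
            p_block[i] = _approx_p(u[i], n1, n2, block[i])
        p[complete] = p_block

    for i in np.flatnonzero(~complete):
        x = tgt[i][~np.isnan(tgt[i])]
        y = ref[i][~np.isnan(ref[i])]
        p[i] = rank_sum_p(x, y)
    return p


# ---------------------------------------------------------------------------
# Top-k variable sites
# ---------------------------------------------------------------------------


def top_variable_sites(beta: BetaMatrix, k: int) -> list[str]:
    """Probe ids of the k most variable sites (sample variance of β,
    missing masked), tie-broken by ascending probe id."""
    arr = beta.values.to_numpy()
    n_ok = (~np.isnan(arr)).sum(axis=1)
    eligible = n_ok >= 2
    if k > int(eligible.sum()):
        raise ValidationError(
            f"k={k} exceeds {int(eligible.sum())} probes with >=2 non-missing values"
        )
    with np.errstate(invalid="ignore"):
        var = np.nanvar(arr, axis=1, ddof=1)
    df = pd.DataFrame({"probe_id": beta.probe_ids, "variance": var})[eligible]
    df = df.sort_values(["variance", "probe_id"], ascending=[False, True], kind="mergesort")
    return df["probe_id"].head(k).tolist()
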