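"""Sample–sample methylome distances, hierarchical trees and heatmap ordering.

Distances are Spearman ρ based: d(i, j) = 1 − ρ(i, j) over the selected
(typically top-k most variable) CpGs, giving values in [0, 2]. Trees are
agglomerative (average or complete linkage) with a deterministic merge
tie-break — among equally distant cluster pairs the pair containing the
lexicographically smallest sample wins — and are exported as Newick with
branch lengths derived from merge heights (leaves at height 0, a child's
branch length = parent height − child height).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .dms_calling import top_variable_sites
from .io_formats import BetaMatrix, ValidationError

MIN_SHARED_PROBES = 3


@dataclass
class TreeResult:
    """A hierarchical tree over samples in Newick form."""

    newick: str
    leaf_labels: list[str]


def validate_distance_matrix(dist: pd.DataFrame) -> pd.DataFrame:
    arr = dist.to_numpy(dtype=float)
    if not np.allclose(np.diag(arr), 0.0):
        raise ValidationError("distance matrix must have a zero diagonal")
    if not np.allclose(arr, arr.T):
        raise ValidationError("distance matrix must be symmetric")
    if list(dist.index) != list(dist.columns):
        raise ValidationError("distance matrix index and columns must match")
    return dist


def spearman_distance(beta: BetaMatrix, probes: list[str]) -> pd.DataFrame:
    """Pairwise 1 − Spearman-ρ distances between samples over given probes.

    Missing values are handled pairwise-complete; a sample pair sharing
    fewer than three probes is an error.
    """
    if len(probes) < MIN_SHARED_PROBES:
        raise ValidationError(f"need >= {MIN_SHARED_PROBES} probes")
    sub = beta.values.loc[probes]
    samples = beta.sample_ids
    n = len(samples)
    d = np.zeros((n, n))
    arr = sub.to_numpy()
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~(np.isnan(arr[:, i]) | np.isnan(arr[:, j]))
            if mask.sum() < MIN_SHARED_PROBES:
                raise ValidationError(
                    f"samples {samples[i]!r}, {samples[j]!r} share fewer than "
                    f"{MIN_SHARED_PROBES} non-missing probes"
                )
            rho = stats.spearmanr(arr[mask, i], arr[mask, j]).statistic
            d[i, j] = d[j, i] = 1.0 - rho
    return validate_distance_matrix(pd.DataFrame(d, index=samples, columns=samples))


# ---------------------------------------------------------------------------
# Agglomerative tree with deterministic tie-break
# ---------------------------------------------------------------------------


@dataclass
class _Cluster:
    members: tuple[str, ...]  # sorted
    size: int
    height: float
    newick: str


def _cluster_distance(
    d: pd.DataFrame, c1: _Cluster, c2: _Cluster, method: str
) -> float:
    block = d.loc[list(c1.members), list(c2.members)].to_numpy()
    if method == "average":
        return float(block.mean())
    if method == "complete":
        return float(block.max())
    raise ValidationError(f"unknown linkage {method!r}; use 'average' or 'complete'")


def cluster_tree(dist: pd.DataFrame, method: str = "average") -> TreeResult:
    """Agglomerative hierarchical tree over a distance matrix, as Newick.

    Merge heights equal the linkage distance; ties are broken by the pair of
    clusters whose (sorted) smallest member labels compare least, so the
    topology is reproducible on fully tied inputs.
    """
    validate_distance_matrix(dist)
    labels = list(dist.index)
    if len(labels) < 2:
        raise ValidationError("need at least two samples to build a tree")
    clusters = [
        _Cluster(members=(lab,), size=1, height=0.0, newick=lab) for lab in labels
    ]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dij = _cluster_distance(dist, clusters[i], clusters[j], method)
                key = (dij, tuple(sorted((clusters[i].members[0], clusters[j].members[0]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (dij, _), i, j = best
        ci, cj = clusters[i], clusters[j]
        # children ordered by smallest member for a stable string
        left, right = sorted((ci, cj), key=lambda c: c.members[0])
        newick = (
            f"({left.newick}:{dij - left.height:.10g},"
            f"{right.newick}:{dij - right.height:.10g})"
        )
        merged = _Cluster(
            members=tuple(sorted(ci.members + cj.members)),
            size=ci.size + cj.size,
            height=dij,
            newick=newick,
        )
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    root = clusters[0]
    return TreeResult(newick=root.newick + ";", leaf_labels=labels)


def clades(newick: str) -> set[frozenset[str]]:
    """Leaf sets of every internal node of a Newick tree (no external parser)."""
    stack: list[list[str]] = []
    out: set[frozenset[str]] = set()
    token = ""
    leaves_in_scope: list[list[str]] = [[]]
    for ch in newick:
        if ch == "(":
            leaves_in_scope.append([])
        elif ch in "),;":
            if token:
                name = token.split(":")[0]
                if name:
                    leaves_in_scope[-1].append(name)
                token = ""
            if ch == ")":
                closed = leaves_in_scope.pop()
                out.add(frozenset(closed))
                leaves_in_scope[-1].extend(closed)
        elif ch == ",":
            pass
        else:
            token += ch
    return out


def is_monophyletic(tree: TreeResult, group: set[str]) -> bool:
    """True if *group* forms a clade (or its complement does, for unrooted
    interpretation of the root split)."""
    group = frozenset(group)
    all_leaves = frozenset(tree.leaf_labels)
    cl = clades(tree.newick)
    return group in cl or (all_leaves - group) in cl


# ---------------------------------------------------------------------------
# Heatmap ordering
# ---------------------------------------------------------------------------


def heatmap_order(
    beta: BetaMatrix,
    probes: list[str],
    center: bool = True,
    method: str = "average",
) -> tuple[list[str], list[str]]:
    """Row (probe) and column (sample) leaf orders from Euclidean hierarchical
    clustering, optionally mean-centering each probe row first (per-CpG
    normalisation for display). Missing values are filled with the row mean
    for ordering purposes only."""
    sub = beta.values.loc[probes]
    arr = sub.to_numpy(dtype=float)
    row_means = np.nanmean(arr, axis=1, keepdims=True)
    filled = np.where(np.isnan(arr), row_means, arr)
    if center:
        filled = filled - filled.mean(axis=1, keepdims=True)
    if len(probes) > 1:
        row_order = leaves_list(linkage(filled, method=method, metric="euclidean"))
    else:
        row_order = np.array([0])
    if filled.shape[1] > 1:
        col_order = leaves_list(linkage(filled.T, method=method, metric="euclidean"))
    else:
        col_order = np.array([0])
    return (
        [probes[i] for i in row_order],
        [beta.sample_ids[i] for i in col_order],
    )


def tree_from_beta(
    beta: BetaMatrix, top_k: int = 5000, method: str = "average"
) -> tuple[pd.DataFrame, TreeResult]:
    """Convenience: top-k variable sites → Spearman distances → tree."""
    k = min(top_k, beta.shape[0])
    probes = top_variable_sites(beta, k)
    dist = spearman_distance(beta, probes)
    return dist, cluster_tree(dist, method=method)
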