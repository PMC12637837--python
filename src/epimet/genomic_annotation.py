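"""Probe-to-genome annotation: promoter windows, CpG-island context and
chromatin states.

Promoters are the 2,000 bases immediately upstream of each protein-coding
transcript's TSS, strand-aware and 1-based inclusive. The TSS base itself is
excluded: on the plus strand the window is [tss-2000, tss-1], on the minus
strand [tss+1, tss+2000]. Windows are clipped at position 1, so a window near
a chromosome start may be shorter than 2,000 bases.

A probe may fall in the promoters of several genes; it is retained for each
of them, but a probe hitting several transcripts of the *same* gene counts
only once for that gene (duplicated CpG sites are excluded from per-gene
counts).
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import ValidationError, STRANDS

logger = logging.getLogger(__name__)

PROMOTER_WINDOW = 2000


def build_promoters(transcripts: pd.DataFrame, window: int = PROMOTER_WINDOW) -> pd.DataFrame:
    """One upstream promoter window per protein-coding transcript.

    Returns columns (gene_id, transcript_id, chromosome, strand, start, end),
    1-based inclusive. Non-protein-coding transcripts are excluded and
    counted in the log.
    """
    bad = set(transcripts["strand"]) - set(STRANDS)
    if bad:
        raise ValidationError(f"unknown strand symbols {sorted(bad)}")
    coding = transcripts[transcripts["biotype"] == "protein_coding"]
    n_excluded = len(transcripts) - len(coding)
    if n_excluded:
        logger.info("build_promoters: excluded %d non-protein-coding transcripts", n_excluded)
    tss = coding["tss"].to_numpy()
    plus = (coding["strand"] == "+").to_numpy()
    start = np.where(plus, tss - window, tss + 1)
    end = np.where(plus, tss - 1, tss + window)
    out = pd.DataFrame(
        {
            "gene_id": coding["gene_id"].to_numpy(),
            "transcript_id": coding["transcript_id"].to_numpy(),
            "chromosome": coding["chromosome"].to_numpy(),
            "strand": coding["strand"].to_numpy(),
            "start": np.maximum(start, 1),
            "end": end,
        }
    )
    out = out[out["end"] >= out["start"]].reset_index(drop=True)
    out.attrs["n_excluded_noncoding"] = n_excluded
    return out


def _point_trees(df: pd.DataFrame, payload_cols: list[str]) -> dict[str, IntervalTree]:
    """IntervalTree per chromosome; our intervals are 1-based inclusive so the
    half-open tree interval is [start, end + 1)."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for row in df.itertuples(index=False):
        trees[row.chromosome].addi(row.start, row.end + 1, tuple(getattr(row, c) for c in payload_cols))
    return trees


def assign_probes(
    manifest: pd.DataFrame,
    promoters: pd.DataFrame,
    states: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Annotate each probe with CpG context, chromatin state and promoter hits.

    CpG context comes from the manifest (not recomputed from sequence). A
    probe overlapping no state interval gets ``unassigned``; a probe on a
    segment boundary takes the interval with the lower start. Promoter hits
    are deduplicated (gene_id, transcript_id) pairs.
    """
    promoter_trees = _point_trees(promoters, ["gene_id", "transcript_id", "start"])
    state_trees = (
        _point_trees(states, ["state", "start"]) if states is not None else {}
    )

    hits_col: list[list[tuple[str, str]]] = []
    state_col: list[str] = []
    for row in manifest.itertuples(index=False):
        tree = promoter_trees.get(row.chromosome)
        if tree is None:
            hits = []
        else:
            hits = sorted({(iv.data[0], iv.data[1]) for iv in tree.at(row.position)})
        hits_col.append(hits)

        stree = state_trees.get(row.chromosome)
        if stree is None:
            state_col.append("unassigned")
        else:
            overlapping = stree.at(row.position)
            if not overlapping:
                state_col.append("unassigned")
            else:
                # safety tie rule: lowest interval start wins
                best = min(overlapping, key=lambda iv: (iv.data[1], iv.data[0]))
                state_col.append(best.data[0])

    out = pd.DataFrame(
        {
            "probe_id": manifest["probe_id"].to_numpy(),
            "cpg_context": manifest["cpg_context"].to_numpy(),
            "chromatin_state": state_col,
            "promoter_hits": hits_col,
        }
    )
    return out


def write_probe_annotation(annotation: pd.DataFrame, path) -> None:
    out = annotation.copy()
    out["promoter_hits"] = out["promoter_hits"].map(
        lambda hits: ";".join(f"{g}|{t}" for g, t in hits)
    )
    out.to_csv(path, sep="\t", index=False)


def read_probe_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    df["promoter_hits"] = df["promoter_hits"].map(
        lambda s: [tuple(h.split("|", 1)) for h in s.split(";")] if s else []
    )
    return df


def count_promoter_dms(dms: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-gene counts of unique promoter DMS CpGs, split by direction.

    A CpG in the promoter windows of several transcripts of one gene counts
    once for that gene; a CpG in the promoters of two genes counts once for
    each. Genes with no promoter DMS are absent from the output.
    """
    dms_probes = set(dms["probe_id"])
    ann_probes = set(annotation["probe_id"])
    if not dms_probes <= ann_probes:
        missing = sorted(dms_probes - ann_probes)[:5]
        raise ValidationError(f"DMS probes missing from annotation (e.g. {missing})")

    direction = dms.set_index("probe_id")["direction"]
    sig = direction[direction != "none"]
    counts: dict[str, dict[str, set]] = defaultdict(lambda: {"hyper": set(), "hypo": set()})
    ann = annotation.set_index("probe_id")["promoter_hits"]
    for probe_id, d in sig.items():
        for gene_id, _transcript in ann.get(probe_id, []):
            counts[gene_id][d].add(probe_id)

    rows = [
        {"gene_id": g, "n_hyper": len(v["hyper"]), "n_hypo": len(v["hypo"])}
        for g, v in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "n_hyper", "n_hypo"])
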