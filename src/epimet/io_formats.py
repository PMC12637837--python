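"""Readers, writers and validated in-memory containers for every table the
pipeline touches.

All genomic positions are 1-based inclusive internally; BED input (0-based,
half-open) is converted on read, and chromosome names are normalised to the
"chr"-prefixed dialect at the boundary. β-values are methylation fractions
β = M/(M+U) in [0, 1]; missing entries are encoded as ``NA`` in TSV, kept as
NaN in memory, and masked downstream rather than imputed. No statistics live
in this module.
"""

from __future__ import annotations

import logging
from collections.abc import Iterator, Mapping
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sample site labels: primary tumor, lymph-node metastasis, lung metastasis.
GROUPS = ("PT", "LN", "LU")

#: CpG-island context classes by distance from CpG-dense islands.
CPG_CONTEXTS = ("island", "shore", "shelf", "open_sea")

#: Summarised chromatin-state labels.
CHROMATIN_STATES = (
    "promoter",
    "enhancer",
    "insulator",
    "heterochromatin",
    "active_transcription",
    "other",
)

STRANDS = ("+", "-")


class ValidationError(ValueError):
    """An input table violated one of its declared invariants."""


def normalize_chromosome(values: pd.Series | Sequence[str]) -> pd.Series:
    """Normalise chromosome names to the chr-prefixed dialect."""
    s = pd.Series(values, dtype="string").str.strip()
    missing = ~s.str.startswith("chr")
    s = s.mask(missing, "chr" + s)
    return s.astype(str)


# ---------------------------------------------------------------------------
# BetaMatrix
# ---------------------------------------------------------------------------


class BetaMatrix:
    """Probes × samples matrix of methylation β-values.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with sample ids as columns. Entries
        must lie in [0, 1] or be NaN (missing).
    dropped_probes
        Probe ids removed at read time because they were absent from a
        supplied manifest; kept for the run log.
    """

    def __init__(self, values: pd.DataFrame, dropped_probes: Sequence[str] = ()):
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValidationError(f"duplicate probe id {dup!r} in beta matrix")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r} in beta matrix")
        arr = values.to_numpy(dtype=float)
        bad = (arr < 0.0) | (arr > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {arr[i, j]!r} outside [0, 1] at probe "
                f"{values.index[i]!r}, sample {values.columns[j]!r}"
            )
        self.values = values.astype(float)
        self.values.index.name = "probe_id"
        self.dropped_probes = list(dropped_probes)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples not in beta matrix: {missing}")
        return BetaMatrix(self.values[list(sample_ids)])

    def __repr__(self) -> str:  # pragma: no cover
        return f"BetaMatrix({self.shape[0]} probes x {self.shape[1]} samples)"


def read_beta_matrix(path, manifest: pd.DataFrame | None = None) -> BetaMatrix:
    """Read a β matrix TSV (first column probe id, header row sample ids).

    If *manifest* is given, probes absent from it are dropped, counted in
    the log and recorded on the returned object.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=True)
    df.index = df.index.astype(str)
    dropped: list[str] = []
    if manifest is not None:
        keep = df.index.isin(manifest["probe_id"])
        dropped = sorted(df.index[~keep])
        if dropped:
            logger.info(
                "read_beta_matrix: dropped %d probes absent from manifest", len(dropped)
            )
        df = df.loc[keep]
    return BetaMatrix(df, dropped_probes=dropped)


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    beta.values.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# Sample sheet, manifest, transcripts, chromatin states, expression table
# ---------------------------------------------------------------------------


def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "group", "cohort"}
    if not required.issubset(df.columns):
        raise ValidationError(f"sample sheet needs columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample id {dup!r} in sample sheet")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValidationError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
    return df.reset_index(drop=True)


def read_sample_sheet(path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, sep="\t", dtype=str))


def check_pairing(beta: BetaMatrix, sheet: pd.DataFrame) -> None:
    """Every sample in the β matrix appears exactly once in the sheet."""
    sheet_ids = set(sheet["sample_id"])
    missing = [s for s in beta.sample_ids if s not in sheet_ids]
    if missing:
        raise ValidationError(f"samples missing from sample sheet: {missing}")


def validate_manifest(
    df: pd.DataFrame, chromosomes: Sequence[str] | None = None
) -> pd.DataFrame:
    required = {"probe_id", "chromosome", "position", "cpg_context"}
    if not required.issubset(df.columns):
        raise ValidationError(f"manifest needs columns {sorted(required)}")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValidationError(f"duplicate probe id {dup!r} in manifest")
    df = df.copy()
    df["chromosome"] = normalize_chromosome(df["chromosome"])
    df["position"] = df["position"].astype(int)
    if (df["position"] < 1).any():
        raise ValidationError("manifest positions must be >= 1 (1-based)")
    bad = set(df["cpg_context"]) - set(CPG_CONTEXTS)
    if bad:
        raise ValidationError(f"unknown cpg_context {sorted(bad)}; expected {CPG_CONTEXTS}")
    if chromosomes is not None:
        declared = set(normalize_chromosome(pd.Series(chromosomes)))
        off = set(df["chromosome"]) - declared
        if off:
            raise ValidationError(f"chromosomes outside declared list: {sorted(off)}")
    return df.reset_index(drop=True)


def read_manifest(path, chromosomes: Sequence[str] | None = None) -> pd.DataFrame:
    return validate_manifest(pd.read_csv(path, sep="\t"), chromosomes=chromosomes)


def validate_transcripts(df: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_id", "transcript_id", "chromosome", "strand", "tss", "biotype"}
    if not required.issubset(df.columns):
        raise ValidationError(f"transcript table needs columns {sorted(required)}")
    if df["transcript_id"].duplicated().any():
        dup = df.loc[df["transcript_id"].duplicated(), "transcript_id"].iloc[0]
        raise ValidationError(f"duplicate transcript id {dup!r}")
    bad = set(df["strand"]) - set(STRANDS)
    if bad:
        raise ValidationError(f"unknown strand symbols {sorted(bad)}; expected {STRANDS}")
    df = df.copy()
    df["chromosome"] = normalize_chromosome(df["chromosome"])
    df["tss"] = df["tss"].astype(int)
    if (df["tss"] < 1).any():
        raise ValidationError("tss must be >= 1 (1-based)")
    return df.reset_index(drop=True)


def read_transcripts(path) -> pd.DataFrame:
    return validate_transcripts(pd.read_csv(path, sep="\t"))


def read_chromatin_bed(path) -> pd.DataFrame:
    """Read a chromatin-state segmentation from BED.

    BED is 0-based half-open; records come back 1-based inclusive with
    columns (chromosome, start, end, state).
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chromosome", "start", "end", "state"],
        usecols=[0, 1, 2, 3],
    )
    if (df["start"] >= df["end"]).any():
        row = df[df["start"] >= df["end"]].iloc[0]
        raise ValidationError(
            f"BED record with start >= end: {row['chromosome']}:{row['start']}-{row['end']}"
        )
    bad = set(df["state"]) - set(CHROMATIN_STATES)
    if bad:
        raise ValidationError(
            f"unknown chromatin states {sorted(bad)}; expected {CHROMATIN_STATES}"
        )
    df = df.copy()
    df["chromosome"] = normalize_chromosome(df["chromosome"])
    df["start"] = df["start"].astype(int) + 1  # to 1-based inclusive
    df["end"] = df["end"].astype(int)
    return df.reset_index(drop=True)


def write_chromatin_bed(df: pd.DataFrame, path) -> None:
    """Write 1-based inclusive state intervals back to BED (0-based half-open)."""
    out = df.copy()
    out["start"] = out["start"].astype(int) - 1
    out[["chromosome", "start", "end", "state"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def validate_expression_table(df: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_id", "base_mean", "log2fc", "p_value"}
    if not required.issubset(df.columns):
        raise ValidationError(f"expression table needs columns {sorted(required)}")
    if (df["base_mean"] < 0).any():
        raise ValidationError("base_mean must be >= 0")
    p = df["p_value"].dropna()
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p_value must be in [0, 1]")
    return df.reset_index(drop=True)


def read_expression_table(path) -> pd.DataFrame:
    return validate_expression_table(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


class GeneSetCollection(Mapping):
    """Named gene sets, as parsed from a GMT file."""

    def __init__(self, sets: Mapping[str, frozenset[str]]):
        for name, members in sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
        self._sets = {name: frozenset(m) for name, m in sets.items()}

    def __getitem__(self, name: str) -> frozenset[str]:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse standard GMT: ``name<TAB>description<TAB>member...`` per line."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"GMT line {lineno}: fewer than 3 fields")
            name, _desc, *members = fields
            if name in sets:
                raise ValidationError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(m for m in members if m)
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# Result-table schemas
# ---------------------------------------------------------------------------

#: Fixed column order per output schema; booleans round-trip via True/False.
SCHEMAS: dict[str, list[str]] = {
    "dms": [
        "probe_id", "mean_beta_reference", "mean_beta_target", "delta_beta",
        "p_value", "q_value", "direction", "is_dms",
    ],
    "gene_methylation": ["gene_id", "n_hyper", "n_hypo", "meth_class"],
    "enrichment": [
        "category", "a", "b", "c", "d", "odds_ratio", "ci_low", "ci_high",
        "p_value", "q_value",
    ],
    "integrated": [
        "gene_id", "class_a", "class_b", "concordant", "expression_direction",
        "epigenetically_regulated",
    ],
}

_BOOL_COLUMNS = {"is_dms", "concordant", "epigenetically_regulated"}


def write_result_table(records: pd.DataFrame, path, schema_name: str) -> None:
    """Write a result table as TSV in the fixed column order of its schema.

    Floats are rendered at full precision (well beyond the documented
    6-significant-digit minimum) so the matching reader round-trips exactly.
    """
    if schema_name not in SCHEMAS:
        raise ValidationError(f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}")
    cols = SCHEMAS[schema_name]
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise ValidationError(f"records missing columns {missing} for schema {schema_name!r}")
    records[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_result_table(path, schema_name: str) -> pd.DataFrame:
    if schema_name not in SCHEMAS:
        raise ValidationError(f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}")
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
    cols = SCHEMAS[schema_name]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"file missing columns {missing} for schema {schema_name!r}")
    for c in _BOOL_COLUMNS & set(cols):
        if df[c].dtype == object:
            df[c] = df[c].map({"True": True, "False": False})
        df[c] = df[c].astype(bool)
    return df[cols]
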