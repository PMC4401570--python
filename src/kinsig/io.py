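"""Tables in, tables out: expression matrices, metadata, filters, assignments.

File formats are plain tab-delimited text. An expression matrix starts
with the annotation columns ``cluster_id, chrom, start, end, strand,
gene_id, biotype, gene_length`` followed by one column per sample;
genomic intervals follow BED conventions (0-based, half-open). Sample
metadata carries ``sample_id, treatment, time_min, replicate,
mapped_tags`` with exactly one row per matrix sample column.

The filters mirror the study design: libraries need at least 500,000
mapped tags, time points at least two biological replicates; protein-
coding CAGE clusters are thresholded at 10 TPM (maximum of the per-time
replicate medians over the course), non-coding clusters at a 3 TPM sum
after relative log expression (RLE, median-of-ratios) normalisation, and
small-RNA rows at a sum of 10 median-normalised reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signatures import SignatureKind

__all__ = [
    "ANNOTATION_COLUMNS",
    "METADATA_COLUMNS",
    "ExpressionMatrix",
    "TimeCourse",
    "SchemaError",
    "ParseError",
    "EmptyDatasetError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_metadata",
    "write_metadata",
    "qc_filter_samples",
    "filter_protein_coding",
    "rle_normalize",
    "filter_noncoding",
    "filter_small_rna",
    "build_time_courses",
    "write_assignments",
    "read_assignments",
]

ANNOTATION_COLUMNS = [
    "cluster_id",
    "chrom",
    "start",
    "end",
    "strand",
    "gene_id",
    "biotype",
    "gene_length",
]
METADATA_COLUMNS = ["sample_id", "treatment", "time_min", "replicate", "mapped_tags"]


class SchemaError(ValueError):
    """Matrix and metadata are inconsistent or a table lacks columns."""


class ParseError(ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


class EmptyDatasetError(ValueError):
    """All samples or time points were removed by filtering."""


@dataclass
class ExpressionMatrix:
    """Cluster annotations plus a clusters x samples value block.

    ``annotations`` is indexed by cluster_id; ``values`` shares that index
    and has one column per sample. Values are TPM for CAGE and read
    counts for small RNA.
    """

    annotations: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.annotations.index.equals(self.values.index):
            raise SchemaError("annotation and value rows must share cluster_ids")
        if self.annotations.index.has_duplicates:
            raise SchemaError("cluster_ids must be unique")
        if (self.values.to_numpy() < 0).any():
            raise SchemaError("expression values must be >= 0")

    @property
    def cluster_ids(self) -> pd.Index:
        return self.annotations.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset(self, cluster_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.annotations.loc[cluster_ids], self.values.loc[cluster_ids])


@dataclass
class TimeCourse:
    """Replicated observations over time for one cluster.

    Medians (midpoint average for an even replicate count) are computed
    from the replicate values on construction.
    """

    cluster_id: str
    times: np.ndarray
    replicates: list[np.ndarray]
    medians: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size == 0:
            raise EmptyDatasetError(f"cluster {self.cluster_id}: no time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"cluster {self.cluster_id}: times must be strictly increasing")
        if self.times[0] != 0:
            raise ValueError(f"cluster {self.cluster_id}: first time point must be 0")
        if len(self.replicates) != self.times.size:
            raise ValueError("one replicate set per time point required")
        self.replicates = [np.asarray(r, dtype=float) for r in self.replicates]
        for t, r in zip(self.times, self.replicates):
            if r.size < 2:
                raise ValueError(
                    f"cluster {self.cluster_id}: time {t} has fewer than 2 replicates"
                )
        self.medians = np.array([float(np.median(r)) for r in self.replicates])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def replicate_matrix(self) -> np.ndarray:
        """Rectangular (n_times, max_reps) array, NaN-padded."""
        width = max(r.size for r in self.replicates)
        out = np.full((self.times.size, width), np.nan)
        for i, r in enumerate(self.replicates):
            out[i, : r.size] = r
        return out


# ---------------------------------------------------------------------------
# readers / writers


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} lacks required columns: {missing}")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ANNOTATION_COLUMNS, "expression matrix")
    ann = df[ANNOTATION_COLUMNS].set_index("cluster_id")
    values = df.drop(columns=ANNOTATION_COLUMNS[1:]).set_index("cluster_id")
    return ExpressionMatrix(ann, values.astype(float))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.annotations.join(matrix.values).reset_index()
    out.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, METADATA_COLUMNS, "sample metadata")
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def _check_consistency(matrix: ExpressionMatrix, metadata: pd.DataFrame) -> None:
    meta_samples = set(metadata["sample_id"])
    matrix_samples = set(matrix.sample_ids)
    if meta_samples != matrix_samples:
        raise SchemaError(
            "matrix columns and metadata rows disagree: "
            f"matrix-only={sorted(matrix_samples - meta_samples)}, "
            f"metadata-only={sorted(meta_samples - matrix_samples)}"
        )
    if metadata["sample_id"].duplicated().any():
        raise SchemaError("duplicate sample_ids in metadata")


# ---------------------------------------------------------------------------
# filters


def qc_filter_samples(
    metadata: pd.DataFrame,
    min_tags: int = 500_000,
    min_reps: int = 2,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop under-sequenced libraries, then under-replicated time points.

    Returns the retained metadata and a log of exclusions with reasons.
    """
    _require_columns(metadata, METADATA_COLUMNS, "sample metadata")
    log: list[str] = []
    low = metadata["mapped_tags"] < min_tags
    for _, row in metadata[low].iterrows():
        log.append(
            f"sample {row['sample_id']}: {row['mapped_tags']} mapped tags < {min_tags}"
        )
    kept = metadata[~low]
    counts = kept.groupby("time_min")["sample_id"].count()
    bad_times = counts[counts < min_reps].index
    for t in bad_times:
        log.append(f"time {t}: fewer than {min_reps} replicates remain")
    kept = kept[~kept["time_min"].isin(bad_times)]
    if kept.empty:
        raise EmptyDatasetError("no time points survive QC filtering")
    return kept.reset_index(drop=True), log


def _per_time_medians(matrix: ExpressionMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """Clusters x times frame of median-across-replicates values."""
    _check_consistency(matrix, metadata)
    groups = metadata.groupby("time_min")["sample_id"].apply(list)
    med = {t: matrix.values[cols].median(axis=1) for t, cols in groups.items()}
    return pd.DataFrame(med)


def filter_protein_coding(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    threshold_tpm: float = 10.0,
) -> ExpressionMatrix:
    """Keep clusters whose per-time median TPM peaks at or above threshold."""
    med = _per_time_medians(matrix, metadata)
    keep = med.max(axis=1) >= threshold_tpm
    return matrix.subset(matrix.cluster_ids[keep])


def rle_normalize(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, pd.Series]:
    """Relative log expression (median-of-ratios) normalisation.

    The reference is the per-row geometric mean over rows positive in all
    samples; each sample's size factor is the median of its ratios to the
    reference, and values are divided by the factor.
    """
    vals = matrix.values
    if vals.shape[1] < 2:
        raise ValueError("RLE normalisation needs at least 2 samples")
    positive = (vals > 0).all(axis=1)
    if not positive.any():
        raise ValueError("RLE normalisation impossible: no row positive in all samples")
    ref = np.exp(np.log(vals[positive]).mean(axis=1))
    factors = vals[positive].div(ref, axis=0).median(axis=0)
    normalized = vals.div(factors, axis=1)
    return ExpressionMatrix(matrix.annotations, normalized), factors


def filter_noncoding(matrix_rle: ExpressionMatrix, min_sum_tpm: float = 3.0) -> ExpressionMatrix:
    """Keep clusters whose RLE-normalised TPM sum over the course >= threshold."""
    keep = matrix_rle.values.sum(axis=1) >= min_sum_tpm
    return matrix_rle.subset(matrix_rle.cluster_ids[keep])


def filter_small_rna(
    count_matrix: ExpressionMatrix,
    min_sum_reads: float = 10.0,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Median-normalise small-RNA counts, then threshold on row sums.

    Each sample is scaled so that its median over rows expressed in all
    samples equals the across-sample median of those medians; rows whose
    normalised sum falls below ``min_sum_reads`` are dropped.
    """
    vals = count_matrix.values
    expressed = (vals > 0).all(axis=1)
    if expressed.any():
        sample_medians = vals[expressed].median(axis=0)
        target = sample_medians.median()
        factors = sample_medians / target
    else:
        factors = pd.Series(1.0, index=vals.columns)
    normalized = vals.div(factors, axis=1)
    keep = normalized.sum(axis=1) >= min_sum_reads
    out = ExpressionMatrix(count_matrix.annotations, normalized).subset(
        count_matrix.cluster_ids[keep]
    )
    return out, factors


# ---------------------------------------------------------------------------
# time courses


def build_time_courses(
    matrix: ExpressionMatrix, metadata: pd.DataFrame
) -> list[TimeCourse]:
    """One TimeCourse per cluster, ordered deterministically by cluster_id."""
    _check_consistency(matrix, metadata)
    by_time = sorted(metadata.groupby("time_min")["sample_id"].apply(list).items())
    times = np.array([t for t, _ in by_time], dtype=float)
    columns = [cols for _, cols in by_time]
    courses = []
    for cid in sorted(matrix.cluster_ids):
        reps = [matrix.values.loc[cid, cols].to_numpy(dtype=float) for cols in columns]
        courses.append(TimeCourse(str(cid), times, reps))
    return courses


# ---------------------------------------------------------------------------
# assignment tables

_VALID_CATEGORIES = {k.value for k in SignatureKind} | {"no_decision"}


def write_assignments(table: pd.DataFrame, path: str | Path) -> None:
    """Write an assignment table as tab-delimited text (NA for missing)."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_assignments(path: str | Path) -> pd.DataFrame:
    """Read an assignment table; malformed categories raise ParseError."""
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message varies
        raise ParseError(str(exc)) from exc
    if "cluster_id" not in df.columns or "category" not in df.columns:
        raise ParseError("assignment table requires cluster_id and category columns", line=1)
    for i, cat in enumerate(df["category"], start=2):
        if pd.isna(cat):
            continue
        if cat not in _VALID_CATEGORIES:
            raise ParseError(f"unknown category {cat!r}", line=i)
    return df
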