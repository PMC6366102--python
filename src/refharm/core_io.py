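"""Expression-matrix container, delimited-text I/O, and gene-space utilities.

The central object is :class:`ExpressionMatrix`: a gene-by-sample numeric
matrix keyed by gene symbols, carrying per-sample platform and biological
labels and an explicit scale flag (``linear`` intensities/counts or ``log2``
units).  Matrices from different platforms are made comparable by
intersecting their gene spaces (:func:`intersect_genes`); sequencing count
matrices can additionally be screened for reliably measured genes with
:func:`filter_reliable_genes`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "FilterReport",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_metadata",
    "write_metadata",
    "intersect_genes",
    "filter_reliable_genes",
]

LINEAR = "linear"
LOG2 = "log2"

UNKNOWN_PLATFORM = "unknown"


class MatrixFormatError(ValueError):
    """Raised when an expression matrix file or object violates the format."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression matrix with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame with gene symbols as the index and sample ids as columns.
    platform
        Per-sample platform label, aligned with ``values.columns``.
    bio_label
        Per-sample biological label (e.g. the reference-mixture types
        A/B/C/D), aligned with ``values.columns``; empty string if unknown.
    scale
        Either ``"linear"`` (non-negative intensities or counts) or
        ``"log2"`` (log2 units, any sign).
    attrs
        Free-form provenance annotations (e.g. imputed gene lists).
    """

    values: pd.DataFrame
    platform: pd.Series | None = None
    bio_label: pd.Series | None = None
    scale: str = LINEAR
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values = self.values.astype(float)
        samples = self.values.columns
        if self.platform is None:
            self.platform = pd.Series(UNKNOWN_PLATFORM, index=samples, dtype=object)
        else:
            self.platform = pd.Series(self.platform).reindex(samples).fillna(UNKNOWN_PLATFORM)
        if self.bio_label is None:
            self.bio_label = pd.Series("", index=samples, dtype=object)
        else:
            self.bio_label = pd.Series(self.bio_label).reindex(samples).fillna("")
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.values.size == 0:
            raise MatrixFormatError("empty expression matrix")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate gene identifiers: {dupes[:5]}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate sample identifiers: {dupes[:5]}")
        if self.scale not in (LINEAR, LOG2):
            raise MatrixFormatError(f"unknown scale {self.scale!r}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise MatrixFormatError("expression values must be finite")
        if self.scale == LINEAR and (arr < 0).any():
            raise MatrixFormatError("linear-scale values must be non-negative")

    # -- accessors --------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            self.platform.copy(),
            self.bio_label.copy(),
            self.scale,
            dict(self.attrs),
        )

    def with_values(self, values: pd.DataFrame | np.ndarray, scale: str | None = None) -> "ExpressionMatrix":
        """Return a sibling matrix with new values but the same metadata."""
        if isinstance(values, np.ndarray):
            values = pd.DataFrame(values, index=self.values.index, columns=self.values.columns)
        return ExpressionMatrix(
            values,
            self.platform.reindex(values.columns),
            self.bio_label.reindex(values.columns),
            self.scale if scale is None else scale,
            dict(self.attrs),
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = set(genes) - set(self.values.index)
        if missing:
            raise KeyError(f"genes absent from matrix: {sorted(missing)[:5]}")
        return self.with_values(self.values.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(samples)],
            self.platform.reindex(samples),
            self.bio_label.reindex(samples),
            self.scale,
            dict(self.attrs),
        )

    # -- scale conversion -------------------------------------------------
    def to_log2(self) -> "ExpressionMatrix":
        """log2(x + 1) of linear values; identity if already in log2 units."""
        if self.scale == LOG2:
            return self
        return self.with_values(np.log2(self.values.to_numpy() + 1.0), scale=LOG2)

    def to_linear(self) -> "ExpressionMatrix":
        """Inverse of :meth:`to_log2` (2**x - 1, clipped at 0)."""
        if self.scale == LINEAR:
            return self
        lin = np.clip(np.exp2(self.values.to_numpy()) - 1.0, 0.0, None)
        return self.with_values(lin, scale=LINEAR)


@dataclass(frozen=True)
class FilterReport:
    """Outcome of the sequencing reliability filter."""

    n_retained: int
    n_total: int
    min_count: float
    min_fraction: float

    @property
    def fraction_retained(self) -> float:
        return self.n_retained / self.n_total


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _read_table(path: Path) -> pd.DataFrame:
    """Read a TSV (or GCT 1.2) gene-by-sample table with checked structure."""
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    skiprows: int | list[int] = 0
    gct = first.startswith("#1.2")
    if gct:
        skiprows = 2  # version line + dimension line
    try:
        df = pd.read_csv(path, sep="\t", skiprows=skiprows, header=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise MatrixFormatError(f"{path}: malformed delimited text ({exc})") from exc
    if df.shape[1] < 2:
        raise MatrixFormatError(f"{path}: header must contain gene column plus >=1 sample (line 1)")
    if gct and df.shape[1] >= 2 and df.columns[1].lower() == "description":
        df = df.drop(columns=df.columns[1])
    # pandas renames duplicate headers (X, X.1); check the raw header line
    with open(path) as fh:
        for _ in range(skiprows if isinstance(skiprows, int) else 0):
            fh.readline()
        raw_header = fh.readline().rstrip("\n").split("\t")
    raw_samples = raw_header[1:]
    if len(set(raw_samples)) != len(raw_samples):
        dupes = sorted({s for s in raw_samples if raw_samples.count(s) > 1})
        raise MatrixFormatError(f"{path}: duplicated sample column names {dupes} (header line)")
    df = df.set_index(df.columns[0])
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise MatrixFormatError(
                f"{path}: non-numeric value for gene {gene!r} in sample {col!r}"
            )
        if converted.isna().any():
            gene = df.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise MatrixFormatError(f"{path}: missing value for gene {gene!r} in sample {col!r}")
        # re-parse with Python's correctly-rounded strtod: pandas' fast C
        # parser can be one ulp off, which breaks bit-exact round-trips
        numeric[col] = np.array([float(v) for v in df[col]])
    return numeric


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata table (columns: sample_id, platform, bio_label)."""
    meta = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "platform"}
    if not required.issubset(meta.columns):
        raise MatrixFormatError(
            f"{path}: metadata needs columns sample_id, platform[, bio_label]; got {list(meta.columns)}"
        )
    if "bio_label" not in meta.columns:
        meta["bio_label"] = ""
    if meta["sample_id"].duplicated().any():
        raise MatrixFormatError(f"{path}: duplicate sample_id entries in metadata")
    return meta.set_index("sample_id")


def write_metadata(matrix: ExpressionMatrix, path: str | Path) -> None:
    meta = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "platform": matrix.platform.to_numpy(),
            "bio_label": matrix.bio_label.to_numpy(),
        }
    )
    meta.to_csv(path, sep="\t", index=False)


def read_expression_matrix(
    path: str | Path,
    metadata_path: str | Path | None = None,
    duplicate_agg: str = "median",
    scale: str = LINEAR,
) -> ExpressionMatrix:
    """Read a gene-by-sample TSV (or GCT 1.2) file into an ExpressionMatrix.

    Duplicate gene rows (multiple probes mapping to one symbol) are collapsed
    per sample with ``duplicate_agg`` (default: median).  Samples missing
    from the metadata table keep platform ``"unknown"``.
    """
    path = Path(path)
    df = _read_table(path)
    if df.index.duplicated().any():
        df = df.groupby(level=0, sort=False).agg(duplicate_agg)
    platform = None
    bio = None
    if metadata_path is not None:
        meta = read_metadata(metadata_path)
        platform = meta["platform"].reindex(df.columns)
        bio = meta["bio_label"].reindex(df.columns)
    return ExpressionMatrix(df, platform, bio, scale=scale)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV with full float precision (round-trip safe)."""
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Gene-space operations
# ---------------------------------------------------------------------------

def intersect_genes(matrices: Iterable[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict all matrices to their common gene set in lexicographic order.

    Cross-platform comparison requires one shared identifier space; the
    lexicographic canonical order makes outputs reproducible regardless of
    input row order.
    """
    mats = list(matrices)
    if not mats:
        raise ValueError("need at least one matrix")
    common: set[str] = set(mats[0].gene_ids)
    for m in mats[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise MatrixFormatError(
            "gene-set intersection is empty; check that matrices use the same "
            "identifier space (gene symbols)"
        )
    order = sorted(common)
    return [m.subset_genes(order) for m in mats]


def filter_reliable_genes(
    counts: ExpressionMatrix,
    min_count: float = 5,
    min_fraction: float = 0.75,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop genes whose sequencing counts are too low to be reliable.

    A gene is retained when its count is >= ``min_count`` in at least
    ``min_fraction`` of samples.  Gene order is preserved.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError(f"min_fraction must be in [0, 1], got {min_fraction}")
    if counts.scale != LINEAR:
        raise ValueError("reliability filter expects linear-scale counts")
    arr = counts.values.to_numpy()
    frac_ok = (arr >= min_count).mean(axis=1)
    keep = frac_ok >= min_fraction
    report = FilterReport(int(keep.sum()), counts.n_genes, min_count, min_fraction)
    if report.n_retained == 0:
        raise MatrixFormatError("reliability filter removed every gene")
    filtered = counts.with_values(counts.values.loc[keep])
    return filtered, report


def concat_samples(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-bind matrices that share an identical gene index and scale."""
    first = matrices[0]
    for m in matrices[1:]:
        if list(m.values.index) != list(first.values.index):
            raise MatrixFormatError("matrices must share an identical gene index")
        if m.scale != first.scale:
            raise MatrixFormatError("matrices must share the same scale")
    values = pd.concat([m.values for m in matrices], axis=1)
    platform = pd.concat([m.platform for m in matrices])
    bio = pd.concat([m.bio_label for m in matrices])
    return ExpressionMatrix(values, platform, bio, first.scale)
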