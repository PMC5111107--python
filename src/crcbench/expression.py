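"""Expression-matrix I/O, probe collapse, centering, and cohort merging.

The analysis-ready object is :class:`ExpressionMatrix`: a log2-scale
genes x samples grid (pandas DataFrame) plus per-sample dataset/platform
tags. Matrices are taken as already MAS5- or RMA-normalized; the
normalization flavor is metadata, not computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SERIES_MATRIX_BEGIN = "!series_matrix_table_begin"
SERIES_MATRIX_END = "!series_matrix_table_end"


class MatrixParseError(ValueError):
    """Raised when an expression file cannot be parsed into a valid matrix."""


@dataclass
class ExpressionMatrix:
    """Log2 genes x samples expression grid with per-sample provenance tags.

    Parameters
    ----------
    values
        DataFrame indexed by gene (or probe) identifier, columns are sample
        identifiers. Missing measurements are NaN.
    dataset_of_origin
        Per-sample dataset tag (e.g. a GEO series accession), aligned to
        ``values.columns``.
    platform
        Per-sample platform tag, aligned to ``values.columns``.
    """

    values: pd.DataFrame
    dataset_of_origin: pd.Series | None = None
    platform: pd.Series | None = None
    log2_scale: bool = True

    def __post_init__(self) -> None:
        cols = self.values.columns
        if cols.duplicated().any():
            dupes = sorted(cols[cols.duplicated()].unique())
            raise MatrixParseError(f"duplicated sample ids: {dupes}")
        if self.dataset_of_origin is None:
            self.dataset_of_origin = pd.Series("unknown", index=cols)
        else:
            self.dataset_of_origin = self.dataset_of_origin.reindex(cols)
        if self.platform is None:
            self.platform = pd.Series("unknown", index=cols)
        else:
            self.platform = self.platform.reindex(cols)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = [s for s in sample_ids if s in self.values.columns]
        return ExpressionMatrix(
            self.values[ids],
            self.dataset_of_origin[ids],
            self.platform[ids],
            self.log2_scale,
        )

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


def _validate_numeric_body(df: pd.DataFrame, path: str) -> pd.DataFrame:
    """Coerce body to float, reporting the coordinates of any bad cell."""
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna() & (df.astype(str).str.strip() != "") \
        if isinstance(df, pd.Series) else coerced.isna() & df.notna()
    if isinstance(bad, pd.DataFrame) and bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise MatrixParseError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at "
            f"row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return coerced.astype(float)


def load_matrix(
    path: str | Path,
    format: str = "tsv",
    dataset: str | None = None,
    platform: str | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples expression table.

    ``format="tsv"`` expects a delimited text file with a header row of sample
    ids and gene ids in the first column (tab or comma separated).
    ``format="series_matrix"`` reads the GEO series-matrix dialect: the numeric
    body between the ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` sentinels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        sep = "\t" if path.suffix.lower() != ".csv" else ","
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(header) != len(set(header)):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise MatrixParseError(
                f"{path}: duplicated sample column(s) {dupes}")
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    elif format == "series_matrix":
        lines = path.read_text().splitlines()
        try:
            start = next(i for i, l in enumerate(lines)
                         if l.strip().startswith(SERIES_MATRIX_BEGIN))
        except StopIteration:
            raise MatrixParseError(
                f"{path}: missing {SERIES_MATRIX_BEGIN} sentinel") from None
        try:
            stop = next(i for i, l in enumerate(lines[start:], start)
                        if l.strip().startswith(SERIES_MATRIX_END))
        except StopIteration:
            stop = len(lines)
        body = lines[start + 1:stop]
        if not body:
            raise MatrixParseError(f"{path}: empty series-matrix body")
        from io import StringIO

        raw = pd.read_csv(StringIO("\n".join(body)), sep="\t", index_col=0,
                          dtype=str)
        raw.columns = [c.strip('"') for c in raw.columns]
        raw.index = [str(i).strip('"') for i in raw.index]
    else:
        raise ValueError(f"unknown format {format!r}")

    if raw.columns.duplicated().any():
        dupes = sorted(raw.columns[raw.columns.duplicated()].unique())
        raise MatrixParseError(f"{path}: duplicated sample column(s) {dupes}")
    if raw.shape[1] == 0:
        raise MatrixParseError(f"{path}: header contains no sample columns")
    values = _validate_numeric_body(raw, str(path))
    n = values.shape[1]
    ds = pd.Series(dataset or path.stem, index=values.columns)
    pl = pd.Series(platform or "unknown", index=values.columns)
    return ExpressionMatrix(values, ds, pl)


def collapse_probes(
    matrix: ExpressionMatrix,
    probe_to_gene: Mapping[str, str],
    preferred_probe: Mapping[str, str] | None = None,
    fallback: str = "max_mean",
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene symbol.

    ``probe_to_gene`` annotates each probe with its gene; probes without an
    entry are dropped (and counted in the log). When ``preferred_probe`` names
    a probe for a gene (JetSet-style "most reliable probe set" selection) that
    probe's row is used verbatim; genes with several probes and no preference
    fall back to the probe with the highest mean expression.
    """
    if fallback != "max_mean":
        raise ValueError(f"unknown fallback {fallback!r}")
    preferred_probe = dict(preferred_probe or {})
    probes = matrix.values.index
    mapped = [p for p in probes if p in probe_to_gene]
    if not mapped:
        raise ValueError("no probe in the matrix is present in the probe map")
    n_dropped = len(probes) - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probe(s)", n_dropped)

    by_gene: dict[str, list[str]] = {}
    for p in mapped:
        by_gene.setdefault(probe_to_gene[p], []).append(p)

    rows = {}
    means = matrix.values.mean(axis=1)
    for gene, plist in by_gene.items():
        pref = preferred_probe.get(gene)
        if pref is not None and pref in plist:
            chosen = pref
        elif len(plist) == 1:
            chosen = plist[0]
        else:
            chosen = means[plist].idxmax()
        rows[gene] = matrix.values.loc[chosen]
    collapsed = pd.DataFrame(rows).T
    collapsed = collapsed.sort_index()
    collapsed.columns = matrix.values.columns
    return ExpressionMatrix(collapsed, matrix.dataset_of_origin,
                            matrix.platform, matrix.log2_scale)


def center_values(
    matrix: ExpressionMatrix,
    mode: str = "gene_median",
    scope: str = "pooled",
) -> ExpressionMatrix:
    """Median-center each gene, pooled or within each dataset of origin.

    After centering, each gene's non-missing values within the chosen scope
    have median 0. ``mode="none"`` returns the matrix unchanged. All-missing
    genes are left missing with a warning.
    """
    if mode == "none":
        return matrix
    if mode != "gene_median":
        raise ValueError(f"unknown centering mode {mode!r}")
    if scope not in ("pooled", "per_dataset"):
        raise ValueError(f"unknown scope {scope!r}")
    values = matrix.values.copy()
    all_missing = values.isna().all(axis=1)
    if all_missing.any():
        logger.warning("center_values: %d all-missing gene(s) left missing",
                       int(all_missing.sum()))
    if scope == "pooled":
        values = values.sub(values.median(axis=1, skipna=True), axis=0)
    else:
        for ds in matrix.dataset_of_origin.unique():
            cols = matrix.dataset_of_origin.index[matrix.dataset_of_origin == ds]
            block = values[cols]
            values[cols] = block.sub(block.median(axis=1, skipna=True), axis=0)
    return ExpressionMatrix(values, matrix.dataset_of_origin, matrix.platform,
                            matrix.log2_scale)


@dataclass
class DuplicateReport:
    """Samples removed during merging, with the retained sample they matched."""

    removed: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["removed_id", "retained_id", "reason", "correlation"]))

    @property
    def removed_ids(self) -> list[str]:
        return list(self.removed["removed_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.removed.to_csv(path, sep="\t", index=False)


def merge_and_dedup(
    matrices: Iterable[ExpressionMatrix],
    correlation_threshold: float = 0.99,
) -> tuple[ExpressionMatrix, DuplicateReport]:
    """Pool matrices over their shared genes and drop redundant samples.

    Two samples are redundant when they share an identifier or when their
    pairwise Pearson correlation over the shared genes reaches
    ``correlation_threshold`` (default 0.99). Within each duplicate group only
    the first-encountered sample is retained; removals are listed in the
    report. Missing values are excluded pairwise from correlations.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices to merge")
    shared = matrices[0].values.index
    for m in matrices[1:]:
        shared = shared.intersection(m.values.index)
    if len(shared) == 0:
        raise ValueError("empty shared gene set across input matrices")
    shared = sorted(shared)

    removed_rows = []
    blocks, ds_parts, pl_parts = [], [], []
    seen_ids: dict[str, str] = {}
    for m in matrices:
        keep = []
        for s in m.values.columns:
            if s in seen_ids:
                removed_rows.append(
                    {"removed_id": s, "retained_id": s,
                     "reason": "identical_id", "correlation": np.nan})
            else:
                seen_ids[s] = s
                keep.append(s)
        if keep:
            blocks.append(m.values.loc[shared, keep])
            ds_parts.append(m.dataset_of_origin[keep])
            pl_parts.append(m.platform[keep])
    pooled = pd.concat(blocks, axis=1)

    # pairwise Pearson over shared genes; greedy first-encountered retention
    corr = pooled.corr(method="pearson", min_periods=2).to_numpy()
    cols = list(pooled.columns)
    retained_mask = np.ones(len(cols), dtype=bool)
    for j in range(len(cols)):
        if not retained_mask[j]:
            continue
        for i in range(j):
            if retained_mask[i] and corr[i, j] >= correlation_threshold:
                retained_mask[j] = False
                removed_rows.append(
                    {"removed_id": cols[j], "retained_id": cols[i],
                     "reason": "expression_correlation",
                     "correlation": float(corr[i, j])})
                break
    kept_cols = [c for c, k in zip(cols, retained_mask) if k]
    report = DuplicateReport(pd.DataFrame(
        removed_rows,
        columns=["removed_id", "retained_id", "reason", "correlation"]))
    merged = ExpressionMatrix(
        pooled[kept_cols],
        pd.concat(ds_parts)[kept_cols],
        pd.concat(pl_parts)[kept_cols],
    )
    if removed_rows:
        logger.info("merge_and_dedup: removed %d redundant sample(s)",
                    len(removed_rows))
    return merged, report


def load_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical annotation table keyed by sample_id.

    Expected columns (missing ones are added as NA): rfs_time (months),
    rfs_event (0/1), stage {I,II,III,IV}, msi {MSI,MSS}, gender, age, grade,
    location, t, n, m.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: clinical table needs a sample_id column")
    df = df.set_index("sample_id")
    for col in ("rfs_time", "rfs_event", "age"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("stage", "msi", "gender", "grade", "location", "t", "n", "m"):
        if col not in df.columns:
            df[col] = pd.NA
    validate_clinical(df)
    return df


def validate_clinical(df: pd.DataFrame) -> None:
    if "rfs_time" in df.columns:
        t = pd.to_numeric(df["rfs_time"], errors="coerce")
        if (t.dropna() < 0).any():
            raise ValueError("rfs_time must be >= 0")
    if "rfs_event" in df.columns:
        e = pd.to_numeric(df["rfs_event"], errors="coerce").dropna()
        if not e.isin([0, 1]).all():
            raise ValueError("rfs_event must be 0/1")
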