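"""Probe-level expression matrices: I/O, validation, and transforms.

The central container is :class:`ExpressionMatrix`, a validated probe x sample
matrix of (usually log2-scale) expression values with ordered, unique probe and
sample identifiers.  Readers accept either the GEO series-matrix dialect
(metadata lines prefixed ``!``, the numeric block fenced by
``!series_matrix_table_begin`` / ``!series_matrix_table_end``) or a plain TSV
with probes in rows and a header of sample ids.

Also houses the qRT-PCR delta-Ct normalization (target Ct minus the Ct of the
reference gene GNB2L1, relative expression ``2**(-dCt)``).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "FormatError",
    "ValidationError",
    "read_series_matrix",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "log2_transform",
    "read_annotation_tsv",
    "collapse_to_gene",
    "delta_ct_normalize",
]


class FormatError(ValueError):
    """A file does not follow the expected on-disk layout."""


class ValidationError(ValueError):
    """Data violate an ExpressionMatrix invariant."""


@dataclass
class ExpressionMatrix:
    """Probe x sample expression matrix with identity and finiteness invariants.

    Parameters
    ----------
    data
        DataFrame with probe ids as the index and sample ids as columns.
    is_log2
        Whether values are on the log2 scale.  Readers set this from config;
        :func:`log2_transform` flips it.
    """

    data: pd.DataFrame
    is_log2: bool = True

    def __post_init__(self) -> None:
        idx = self.data.index.astype(str)
        cols = self.data.columns.astype(str)
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate probe id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            n_bad = int((~np.isfinite(values)).sum())
            raise ValidationError(f"{n_bad} non-finite expression values")
        self.data = pd.DataFrame(values, index=idx, columns=cols)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_probes(self, probe_ids: list[str]) -> "ExpressionMatrix":
        missing = [p for p in probe_ids if p not in self.data.index]
        if missing:
            raise KeyError(f"probes not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[probe_ids], is_log2=self.is_log2)


def _strip_quotes(s: str) -> str:
    # GEO convention: one optional layer of double quotes around each field.
    if len(s) >= 2 and s[0] == '"' and s[-1] == '"':
        return s[1:-1]
    return s


def _finalize_frame(
    frame: pd.DataFrame, is_log2: bool, missing: str
) -> ExpressionMatrix:
    if frame.isna().any().any():
        if missing == "reject":
            n = int(frame.isna().sum().sum())
            raise ValidationError(
                f"{n} missing expression values (set missing='row_mean' to impute)"
            )
        elif missing == "row_mean":
            row_means = frame.mean(axis=1)
            frame = frame.apply(lambda col: col.fillna(row_means))
        else:
            raise ValueError(f"unknown missing-value policy: {missing!r}")
    return ExpressionMatrix(frame, is_log2=is_log2)


def read_series_matrix(
    path, is_log2: bool = True, missing: str = "reject"
) -> ExpressionMatrix:
    """Parse the expression block of a GEO series-matrix text file.

    Metadata lines (prefix ``!``) outside the table fence are skipped.  The
    first row inside the fence carries sample ids, the first column probe ids.
    Fields may be wrapped in one layer of double quotes.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        begin = next(
            i for i, ln in enumerate(lines)
            if ln.startswith("!series_matrix_table_begin")
        )
        end = next(
            i for i, ln in enumerate(lines)
            if ln.startswith("!series_matrix_table_end")
        )
    except StopIteration:
        raise FormatError(
            f"{path}: missing !series_matrix_table_begin/_end delimiters"
        ) from None
    if end <= begin + 1:
        raise FormatError(f"{path}: empty series-matrix table")
    block = lines[begin + 1 : end]
    header = [_strip_quotes(f) for f in block[0].split("\t")][1:]
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    for ln in block[1:]:
        fields = ln.split("\t")
        probe_ids.append(_strip_quotes(fields[0]))
        rows.append(
            [float(f) if f not in ("", "null", "NA") else np.nan
             for f in (_strip_quotes(x) for x in fields[1:])]
        )
    frame = pd.DataFrame(rows, index=probe_ids, columns=header, dtype=float)
    return _finalize_frame(frame, is_log2, missing)


def read_matrix_tsv(path, is_log2: bool = True, missing: str = "reject") -> ExpressionMatrix:
    """Read a plain TSV (probes in rows, header = sample ids)."""
    frame = pd.read_csv(path, sep="\t", index_col=0,
                        float_precision="round_trip")
    return _finalize_frame(frame, is_log2, missing)


def write_matrix_tsv(matrix: ExpressionMatrix, path) -> None:
    """Write the canonical TSV representation (17 significant digits, lossless)."""
    matrix.data.to_csv(path, sep="\t", float_format="%.17g", index_label="probe_id")


def log2_transform(matrix: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Return a new matrix with each value v replaced by log2(v + offset)."""
    if matrix.is_log2:
        raise ValueError("matrix is already on the log2 scale")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    shifted = matrix.values + offset
    if np.any(shifted <= 0):
        raise ValueError(
            "nonpositive value after offset; log2 undefined (increase offset)"
        )
    out = pd.DataFrame(
        np.log2(shifted), index=matrix.data.index, columns=matrix.data.columns
    )
    return ExpressionMatrix(out, is_log2=True)


def read_annotation_tsv(path) -> pd.Series:
    """Read a probe annotation TSV (columns probe_id, gene_symbol).

    Returns a Series mapping probe_id -> gene_symbol.  Empty symbols mark
    unannotated probes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"probe_id", "gene_symbol"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns probe_id, gene_symbol")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValidationError(f"duplicate probe_id in annotation: {dup!r}")
    return pd.Series(df["gene_symbol"].values, index=df["probe_id"].values)


def collapse_to_gene(
    matrix: ExpressionMatrix, annotation: pd.Series, rule: str = "best_probe"
) -> ExpressionMatrix:
    """Collapse probes to gene symbols.

    ``best_probe`` keeps, per gene, the probe with the highest variance across
    samples; ``mean`` averages all probes of a gene.  Probes without a gene
    symbol are dropped (count logged).
    """
    if rule not in ("best_probe", "mean"):
        raise ValueError(f"unknown collapse rule: {rule!r}")
    ann = annotation.reindex(matrix.probe_ids).fillna("")
    keep = ann[ann != ""]
    if keep.empty:
        raise ValidationError("no matrix probe has a gene annotation")
    n_dropped = matrix.n_probes - len(keep)
    if n_dropped:
        logger.info("collapse_to_gene: dropped %d unannotated probes", n_dropped)
    sub = matrix.data.loc[keep.index]
    if rule == "mean":
        collapsed = sub.groupby(keep).mean()
    else:
        variances = sub.var(axis=1, ddof=1)
        best = (
            pd.DataFrame({"gene": keep, "var": variances})
            .sort_values(["gene", "var"], ascending=[True, False])
            .groupby("gene")
            .head(1)
        )
        collapsed = sub.loc[best.index]
        collapsed.index = best["gene"].values
        collapsed = collapsed.sort_index()
    return ExpressionMatrix(collapsed, is_log2=matrix.is_log2)


def delta_ct_normalize(ct: pd.DataFrame) -> pd.DataFrame:
    """Delta-Ct normalization against a reference gene (GNB2L1 in this assay).

    Expects columns ``sample_id``, ``target_ct``, ``reference_ct``; returns a
    frame with ``delta_ct = target_ct - reference_ct`` and
    ``rel_expr = 2**(-delta_ct)``.
    """
    required = {"sample_id", "target_ct", "reference_ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    bad = ct[ct["reference_ct"].isna() | ct["target_ct"].isna()]
    if not bad.empty:
        raise ValueError(
            f"missing Ct for samples: {list(bad['sample_id'])}"
        )
    vals = ct[["target_ct", "reference_ct"]].to_numpy(dtype=float)
    if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
        raise ValueError("Ct values must be positive and finite")
    out = ct[["sample_id"]].copy()
    out["delta_ct"] = ct["target_ct"].to_numpy() - ct["reference_ct"].to_numpy()
    out["rel_expr"] = np.exp2(-out["delta_ct"])
    return out
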