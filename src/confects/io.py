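"""Readers and writers for stats tables, expression matrices and results.

Tables are tab- or comma-separated text with a header row; the delimiter
is sniffed from the header line (anything else is an error — no silent
guessing).  Output CSVs carry a provenance header of ``#``-prefixed
comment lines (tool version, parameters, seed) which can be suppressed
for strict-CSV consumers.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .moderation import ExpressionMatrix, GeneStats

__all__ = [
    "read_stats_table",
    "write_stats_table",
    "read_expression_matrix",
    "write_ranked_csv",
]

REQUIRED_STATS_COLUMNS = ("gene_id", "effect", "se", "df")


def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        while header.startswith("#"):
            header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise ValueError(
        f"{path}: could not detect a tab or comma delimiter in the header"
    )


def read_stats_table(path) -> GeneStats:
    """Read a per-gene statistics table (gene_id, effect, se, df).

    Rows with non-positive standard error, non-positive degrees of
    freedom, or non-finite numeric fields are dropped with a warning that
    reports the count.  Duplicate gene ids or a missing required column
    are errors.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    for col in REQUIRED_STATS_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["gene_id"].duplicated().any():
        dups = df["gene_id"][df["gene_id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate gene ids {dups[:5]}")
    num = df[["effect", "se", "df"]].apply(pd.to_numeric, errors="coerce")
    good = (
        np.isfinite(num).all(axis=1) & (num["se"] > 0) & (num["df"] > 0)
    ).to_numpy()
    n_bad = int((~good).sum())
    if n_bad:
        warnings.warn(
            f"{path}: dropped {n_bad} row(s) with invalid statistics "
            "(non-finite values, se <= 0, or df <= 0)",
            RuntimeWarning,
        )
    df = df.loc[good]
    num = num.loc[good]
    return GeneStats(
        df["gene_id"].to_numpy(object),
        num["effect"].to_numpy(float),
        num["se"].to_numpy(float),
        num["df"].to_numpy(float),
    )


def write_stats_table(stats: GeneStats, path) -> None:
    """Write GeneStats as a TSV with columns gene_id, effect, se, df."""
    stats.to_frame().to_csv(path, sep="\t", index=False)


def read_expression_matrix(path, group_b=None, sample_sheet=None) -> ExpressionMatrix:
    """Read a genes x samples log2-expression matrix.

    First column = gene id, remaining header fields = sample names.  The
    group assignment comes either from ``group_b`` (iterable of sample
    names forming group B) or from a two-column sample sheet
    (sample, group).
    """
    sep = _sniff_sep(path)
    frame = pd.read_csv(path, sep=sep, comment="#", index_col=0)
    samples = [str(c) for c in frame.columns]
    if (group_b is None) == (sample_sheet is None):
        raise ValueError("provide exactly one of group_b or sample_sheet")
    if sample_sheet is not None:
        sheet = pd.read_csv(sample_sheet, sep=_sniff_sep(sample_sheet), comment="#")
        if sheet.shape[1] < 2:
            raise ValueError(f"{sample_sheet}: expected columns (sample, group)")
        mapping = dict(zip(sheet.iloc[:, 0].astype(str), sheet.iloc[:, 1].astype(str)))
        missing = [s for s in samples if s not in mapping]
        if missing:
            raise ValueError(f"{sample_sheet}: no group for sample(s) {missing}")
        group = np.array([mapping[s] for s in samples])
    else:
        group_b = {str(s) for s in group_b}
        unknown = group_b - set(samples)
        if unknown:
            raise ValueError(f"group-B sample(s) not in matrix: {sorted(unknown)}")
        group = np.array(["B" if s in group_b else "A" for s in samples])
    return ExpressionMatrix.from_frame(frame, group)


def _provenance_lines(params: dict) -> list[str]:
    items = " ".join(f"{k}={v}" for k, v in params.items())
    return [f"# confects {__version__}", f"# {items}"]


def write_ranked_csv(result, path, *, provenance: bool = True,
                     extra_params: dict | None = None) -> None:
    """Write a ConfectResults ranking as CSV.

    Columns: rank, gene_id, confect, effect, se, df, p_zero, in rank
    order; a missing confect is an empty field.
    """
    table = result.table
    params = {
        "fdr": result.params.fdr,
        "step": result.params.step,
        "max_e": result.params.max_e,
        "n_with_confect": result.n_with_confect,
    }
    if extra_params:
        params.update(extra_params)
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if provenance:
            fh.write("\n".join(_provenance_lines(params)) + "\n")
        table.to_csv(fh, index=False)
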