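"""Count-based CpG methylation calls: parsing, filtering, concordance.

Handles bismark-coverage-style files (tab-separated: chromosome, start,
end, methylation percent, count methylated, count unmethylated; 1-based
inclusive coordinates with start = end for a CpG).  Calls are assumed
already destranded.  Agreement between paired methylomes (e.g. CD14+ vs
unselected mononuclear cells from one subject) is measured with Lin's
concordance correlation coefficient

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (x_bar - y_bar)^2)

using population (1/n) moments, which penalizes both imprecision and
location/scale shift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "read_coverage_file",
    "write_coverage_file",
    "filter_coverage",
    "intersect_callsets",
    "concordance_ccc",
    "variable_site_cluster",
    "CCCResult",
]

logger = logging.getLogger(__name__)

_COLUMNS = ["chromosome", "start", "end", "percent", "count_meth", "count_unmeth"]


def _normalize_chrom(series: pd.Series) -> pd.Series:
    """Strip a 'chr' prefix so files from either convention intersect."""
    s = series.astype(str)
    stripped = s.str.replace(r"^chr", "", regex=True, case=False)
    if (stripped != s).any():
        logger.info("normalized 'chr'-prefixed chromosome names")
    return stripped


def read_coverage_file(path) -> pd.DataFrame:
    """Parse a bismark-style coverage file into a call table.

    Returns a DataFrame with columns ``chromosome``, ``position`` (1-based),
    ``meth_count``, ``total_count`` and ``percent``.  A percent column
    disagreeing with the counts by more than 0.5 triggers a warning (the
    counts win).  Malformed lines and negative counts raise with the line
    number.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected 6 tab-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                percent = float(parts[3])
                meth, unmeth = int(parts[4]), int(parts[5])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if meth < 0 or unmeth < 0:
                raise ValueError(f"{path}: line {lineno}: negative count")
            total = meth + unmeth
            if total > 0 and abs(percent - 100.0 * meth / total) > 0.5:
                logger.warning(
                    "%s: line %d: percent %.2f inconsistent with counts %d/%d",
                    path, lineno, percent, meth, total,
                )
            records.append((chrom, start, meth, total, percent))
    calls = pd.DataFrame(
        records, columns=["chromosome", "position", "meth_count",
                          "total_count", "percent"]
    )
    calls["chromosome"] = _normalize_chrom(calls["chromosome"])
    return calls


def write_coverage_file(calls: pd.DataFrame, path) -> None:
    """Write a call table in bismark coverage format (start = end = position)."""
    with open(path, "w") as fh:
        for row in calls.itertuples(index=False):
            unmeth = row.total_count - row.meth_count
            pct = 100.0 * row.meth_count / row.total_count if row.total_count else 0.0
            fh.write(
                f"{row.chromosome}\t{row.position}\t{row.position}\t"
                f"{pct:.6g}\t{row.meth_count}\t{unmeth}\n"
            )


def filter_coverage(calls: pd.DataFrame, min_reads: int = 10) -> pd.DataFrame:
    """Retain sites covered by at least ``min_reads`` total reads."""
    return calls[calls["total_count"] >= min_reads].reset_index(drop=True)


def intersect_callsets(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Inner join of two call sets on (chromosome, position).

    Returns one row per shared site, columns suffixed ``_a`` / ``_b``,
    ordered by coordinate, with ``frac_a`` / ``frac_b`` methylation
    fractions.
    """
    merged = a.merge(
        b, on=["chromosome", "position"], suffixes=("_a", "_b"), how="inner"
    ).sort_values(["chromosome", "position"], ignore_index=True)
    for side in ("a", "b"):
        tot = merged[f"total_count_{side}"]
        merged[f"frac_{side}"] = np.where(
            tot > 0, merged[f"meth_count_{side}"] / tot, np.nan
        )
    return merged


@dataclass
class CCCResult:
    """Lin's concordance correlation coefficient with its Pearson companion."""

    rho_c: float
    pearson_r: float
    n_sites: int


def concordance_ccc(x, y, sample_moments: bool = False) -> CCCResult:
    """Lin's concordance correlation coefficient between paired vectors.

    Population (1/n) moments by default, per the original definition;
    ``sample_moments`` switches to the n-1 variant (the coefficient is then
    2 s_xy / (s_x^2 + s_y^2 + n/(n-1) (x_bar-y_bar)^2)-free plain plug-in
    of n-1 moments, shown for comparison only).

    Conventions for degenerate inputs: both vectors constant and equal
    gives rho_c = 1, constant and unequal gives 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D vectors, n >= 2")
    ddof = 1 if sample_moments else 0
    sx2 = float(np.var(x, ddof=ddof))
    sy2 = float(np.var(y, ddof=ddof))
    sxy = float(np.cov(x, y, ddof=ddof)[0, 1]) if (sx2 > 0 or sy2 > 0) else 0.0
    mean_diff = float(np.mean(x) - np.mean(y))
    denom = sx2 + sy2 + mean_diff ** 2
    if denom == 0:
        return CCCResult(rho_c=1.0, pearson_r=1.0, n_sites=len(x))
    if sx2 == 0 and sy2 == 0:
        return CCCResult(rho_c=0.0, pearson_r=0.0, n_sites=len(x))
    rho_c = 2.0 * sxy / denom
    if sx2 > 0 and sy2 > 0:
        r = sxy / np.sqrt(sx2 * sy2)
    else:
        r = 0.0
    return CCCResult(rho_c=float(rho_c), pearson_r=float(r), n_sites=len(x))


def variable_site_cluster(
    percent_matrix: pd.DataFrame, sd_threshold: float = 30.0, k: int | None = None
):
    """Ward-cluster samples on the most variable CpG sites.

    ``percent_matrix`` is sites x samples on the percent (0-100) scale;
    fraction-scale input (everything within [0, 1]) is rescaled with a
    warning.  Sites with SD above ``sd_threshold`` are retained; with none,
    an error is raised.  Returns ``(labels, linkage_matrix)`` from
    :func:`methstrat.clustering.ward_cluster` (k defaults to 2 so paired
    designs split; pass k explicitly for other uses).
    """
    from .clustering import ward_cluster

    mat = percent_matrix.astype(float)
    if float(np.nanmax(mat.to_numpy())) <= 1.0:
        logger.warning("input looks fraction-scaled; rescaling to percent")
        mat = mat * 100.0
    sd = mat.std(axis=1, ddof=1)
    keep = mat.loc[sd > sd_threshold]
    if keep.empty:
        raise ValueError("no variable sites above the SD threshold")
    return ward_cluster(keep, k=(k if k is not None else 2))
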