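"""Moderated two-group differential testing and downstream gene projection.

Differential methylation is tested on M-values and differential expression
on log2(TPM + 1), both with an empirical-Bayes moderated t-statistic: the
per-feature residual variance s_g^2 is shrunk toward a prior s0^2 with
prior degrees of freedom d0,

    s_tilde^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and the moderated t uses d_g + d0 degrees of freedom.  The hyperparameters
(d0, s0^2) are estimated by moment matching of a scaled-F distribution to
the observed s_g^2 on the log scale (digamma/trigamma inversion), the
canonical construction for this class of tests.

Significance calls use p < 0.05 (strict) plus |delta beta| >= 0.1
(inclusive) for methylation probes; p < 0.05 alone for expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist

__all__ = [
    "ModeratedTestResult",
    "moderated_two_group_test",
    "call_dmps",
    "call_de_genes",
    "project_to_promoter_genes",
    "overlap_gene_lists",
    "expression_cluster_prep",
]

_D0_CAP = 1e6  # represents the no-residual-heterogeneity (d0 -> inf) limit


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the standard asymptotic start x ~ 1/y + 0.5 and the update in
    terms of trigamma/tetragamma; converges in a handful of steps for the
    magnitudes that arise from log-variance moments.
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float):
    """Moment-matching fit of a scaled F prior to sample variances.

    Returns (d0, s0_sq).  Features with exactly zero variance are excluded
    from the moment fit (they carry no scale information on the log scale)
    but still receive shrinkage from the fitted prior.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return _D0_CAP, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    resid = e_var - _trigamma(df / 2.0)
    if resid <= 0:
        d0 = _D0_CAP
    else:
        d0 = min(2.0 * _trigamma_inverse(resid), _D0_CAP)
    s0_sq = float(np.exp(e_bar + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


@dataclass
class ModeratedTestResult:
    """Per-feature moderated two-group test results.

    ``table`` is indexed by feature id with columns ``mean_diff`` (group 2
    minus group 1 on the tested scale), ``t_moderated``, ``p``, ``s2`` (raw
    residual variance) and, when a beta matrix was supplied, ``delta_beta``
    (group mean beta difference).  ``d0`` and ``s0_sq`` are the shared
    empirical-Bayes hyperparameters.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    df_residual: float


def moderated_two_group_test(
    data: pd.DataFrame,
    groups,
    beta: pd.DataFrame | None = None,
    d0_override: float | None = None,
) -> ModeratedTestResult:
    """Empirical-Bayes moderated t-test between two groups, per feature.

    Parameters
    ----------
    data
        Features x samples matrix on the testing scale (M-values for
        methylation, log2(TPM+1) for expression).
    groups
        Binary labels aligned with ``data`` columns; the contrast is
        group-with-larger-label minus group-with-smaller-label.
    beta
        Optional features x samples beta matrix from which the group mean
        beta difference (``delta_beta``) is computed for methylation calls.
    d0_override
        Force the prior degrees of freedom (0 recovers the ordinary
        per-feature t; values >= the cap give the pooled-prior limit where
        every variance is replaced by s0^2).  Used for limit checks.
    """
    groups = pd.Series(np.asarray(groups), index=data.columns)
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError("exactly two groups are required")
    idx1 = groups.index[groups == levels[0]]
    idx2 = groups.index[groups == levels[1]]
    n1, n2 = len(idx1), len(idx2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two samples")

    X1 = data[idx1].to_numpy(dtype=float)
    X2 = data[idx2].to_numpy(dtype=float)
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    diff = m2 - m1
    df = n1 + n2 - 2
    ss = ((X1 - m1[:, None]) ** 2).sum(axis=1) + ((X2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    se_factor = np.sqrt(1.0 / n1 + 1.0 / n2)

    if d0_override is not None:
        if d0_override < 0:
            raise ValueError("d0_override must be non-negative")
        d0 = min(float(d0_override), _D0_CAP)
        _, s0_sq = _fit_f_dist(s2, df)
    else:
        d0, s0_sq = _fit_f_dist(s2, df)

    if d0 >= _D0_CAP:
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = _D0_CAP
    elif d0 == 0:
        s2_tilde = s2
        df_total = df
    else:
        s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = diff / (np.sqrt(s2_tilde) * se_factor)
    t_mod = np.where(np.isnan(t_mod), 0.0, t_mod)  # 0/0: no evidence
    p = 2.0 * t_dist.sf(np.abs(t_mod), df_total)
    p = np.where(diff == 0, 1.0, p)

    table = pd.DataFrame(
        {"mean_diff": diff, "t_moderated": t_mod, "p": p, "s2": s2},
        index=data.index,
    )
    if beta is not None:
        B1 = beta.loc[data.index, idx1].to_numpy(dtype=float)
        B2 = beta.loc[data.index, idx2].to_numpy(dtype=float)
        table["delta_beta"] = B2.mean(axis=1) - B1.mean(axis=1)
    return ModeratedTestResult(table=table, d0=float(d0), s0_sq=float(s0_sq),
                               df_residual=float(df))


def call_dmps(
    result: ModeratedTestResult,
    p_threshold: float = 0.05,
    delta_beta_min: float = 0.1,
) -> pd.Index:
    """Differentially methylated probes: p < threshold AND |delta beta| >= min.

    The p cutoff is strict and the effect-size cutoff inclusive, matching
    the "p-value < 0.05 and a difference of at least 0.1" convention.
    Requires ``delta_beta`` in the result table.
    """
    tab = result.table
    if "delta_beta" not in tab.columns:
        raise ValueError("delta_beta column required; pass beta= to the test")
    keep = (tab["p"] < p_threshold) & (tab["delta_beta"].abs() >= delta_beta_min)
    return tab.index[keep]


def call_de_genes(result: ModeratedTestResult, p_threshold: float = 0.05) -> pd.Index:
    """Differentially expressed genes: p < threshold (strict)."""
    return result.table.index[result.table["p"] < p_threshold]


def drop_all_zero_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Remove genes with zero expression in every sample (untestable)."""
    return expr.loc[(expr != 0).any(axis=1)]


def project_to_promoter_genes(features, probe_gene_map: pd.DataFrame) -> list:
    """Unique genes whose promoter contains at least one of the features.

    ``probe_gene_map`` is the two-column (probe_id, gene_id) mapping from
    :func:`methstrat.preprocessing.annotate_promoters`.  Output is sorted
    and deduplicated for determinism.
    """
    features = set(features)
    hit = probe_gene_map[probe_gene_map["probe_id"].isin(features)]
    return sorted(set(hit["gene_id"]))


def overlap_gene_lists(a, b) -> list:
    """Sorted, deduplicated intersection of two gene lists."""
    return sorted(set(a) & set(b))


def expression_cluster_prep(
    expr: pd.DataFrame, gene_set, sd_cutoff: float = 2.5
) -> pd.DataFrame:
    """Restrict, variance-filter and median-center expression for clustering.

    Keeps genes in ``gene_set`` whose across-sample SD (n-1 denominator)
    exceeds ``sd_cutoff`` — discarding low/invariant genes — then subtracts
    each gene's median so downstream Ward clustering sees centered profiles.
    """
    present = [g for g in expr.index if g in set(gene_set)]
    sub = expr.loc[present]
    sd = sub.std(axis=1, ddof=1)
    sub = sub.loc[sd > sd_cutoff]
    return sub.sub(sub.median(axis=1), axis=0)
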