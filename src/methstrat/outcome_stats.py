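"""Outcome association statistics for methylation-cluster cohorts.

The primary endpoint is the binary 4-year event indicator.  Association
with cluster membership and clinical covariates is assessed by logistic
regression with likelihood-ratio testing; per-group event proportions get
exact (Clopper-Pearson) binomial confidence intervals; cluster-by-category
contingency tables get the Freeman-Halton generalization of Fisher's exact
test; survival curves use the Kaplan-Meier product-limit estimator.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.special import gammaln
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

__all__ = [
    "RegressionResult",
    "logistic_fit",
    "logistic_fit_formula",
    "lrt_pvalue",
    "odds_ratio_2x2",
    "clopper_pearson",
    "fisher_exact_rxc",
    "kaplan_meier",
    "cluster_event_summary",
]


@dataclass
class RegressionResult:
    """A fitted logistic regression.

    ``odds_ratios`` are ``exp(coefficients)``; confidence bounds are on the
    odds-ratio scale.  ``separation_flag`` marks fits where quasi-complete
    separation made coefficients diverge (estimates are then unreliable and
    the flag should be surfaced, not hidden).
    """

    terms: list
    coefficients: pd.Series
    loglik: float
    nobs: int
    df_model: int
    conf_int: pd.DataFrame | None = None
    separation_flag: bool = False
    lrt_p: dict = field(default_factory=dict)

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.coefficients)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "coef": self.coefficients,
                "OR": self.odds_ratios,
            }
        )
        if self.conf_int is not None:
            out["ci_low"] = np.exp(self.conf_int.iloc[:, 0])
            out["ci_high"] = np.exp(self.conf_int.iloc[:, 1])
        return out


_SEPARATION_COEF = 15.0  # |log-odds| beyond this is treated as divergence


def logistic_fit(y, X) -> RegressionResult:
    """Maximum-likelihood logistic regression.

    Parameters
    ----------
    y
        Binary outcome vector (0/1); rows with missing outcome or covariates
        are dropped listwise.
    X
        Design matrix (DataFrame); an intercept column named ``Intercept``
        is added when absent.  Categorical columns must be pre-coded
        (see :func:`logistic_fit_formula` for treatment coding from a
        sample table).

    Fitting is iteratively reweighted least squares via the binomial GLM;
    perfect separation is reported through ``separation_flag`` rather than
    raising, so degenerate saturated fits remain inspectable.
    """
    X = pd.DataFrame(X).copy()
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep], X[keep]
    if "Intercept" not in X.columns:
        X.insert(0, "Intercept", 1.0)
    if len(y) < X.shape[1]:
        raise ValueError("fewer observations than parameters")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=100, tol=1e-10)

    coefs = res.params
    flag = bool(np.any(np.abs(coefs) > _SEPARATION_COEF) or not res.converged)
    conf = None
    if not flag:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            conf = res.conf_int()
    return RegressionResult(
        terms=list(X.columns),
        coefficients=coefs,
        loglik=float(res.llf),
        nobs=int(res.nobs),
        df_model=int(X.shape[1]),
        conf_int=conf,
        separation_flag=flag,
    )


def _design_from_terms(samples: pd.DataFrame, terms: list) -> pd.DataFrame:
    """Treatment-coded design matrix; first-seen level is the reference."""
    cols = {}
    for term in terms:
        col = samples[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            if isinstance(col.dtype, pd.CategoricalDtype):
                levels = [l for l in col.cat.categories if (col == l).any()]
            else:
                levels = list(pd.unique(col.dropna()))
            for lev in levels[1:]:
                cols[f"{term}[{lev}]"] = (col == lev).astype(float).where(col.notna())
        else:
            cols[term] = col.astype(float)
    return pd.DataFrame(cols, index=samples.index)


def logistic_fit_formula(
    samples: pd.DataFrame, outcome: str, terms: list, lrt: bool = True
) -> RegressionResult:
    """Fit ``outcome ~ terms`` from a sample table with treatment coding.

    String / categorical terms are expanded to indicator columns against the
    first level as reference.  When ``lrt`` is set, a per-term
    likelihood-ratio p-value is computed by refitting without that term
    (all its levels at once) on the same observations.
    """
    y = samples[outcome]
    X = _design_from_terms(samples, terms)
    keep = y.notna() & X.notna().all(axis=1)
    full = logistic_fit(y[keep], X[keep])
    if lrt:
        for term in terms:
            drop = [c for c in X.columns if c == term or c.startswith(f"{term}[")]
            Xr = X[keep].drop(columns=drop)
            reduced = logistic_fit(y[keep], Xr)
            full.lrt_p[term] = lrt_pvalue(full, reduced)
    return full


def lrt_pvalue(full: RegressionResult, reduced: RegressionResult) -> float:
    """Likelihood-ratio p-value for nested logistic models.

    ``p = P(chi2_df > 2 (llf_full - llf_reduced))`` with df the parameter
    difference.  A reduced model fitting better than the full one (beyond
    numerical tolerance) indicates non-nested models or a failed fit.
    """
    stat = 2.0 * (full.loglik - reduced.loglik)
    df = full.df_model - reduced.df_model
    if df <= 0:
        raise ValueError("reduced model must have fewer parameters than full")
    if stat < -1e-6:
        raise ValueError(
            f"full model log-likelihood below reduced ({stat / 2:.3g}); "
            "models are not nested or a fit failed"
        )
    return float(chi2.sf(max(stat, 0.0), df))


# ---------------------------------------------------------------------------
# 2x2 odds ratios


def _table_loglik(table, beta_val):
    """Profile log-likelihood of the log-odds-ratio for two binomials."""
    (a, b), (c, d) = table
    n1, n2 = a + b, c + d

    def nll(alpha):
        p1 = 1.0 / (1.0 + np.exp(-alpha))
        p2 = 1.0 / (1.0 + np.exp(-(alpha + beta_val)))
        eps = 1e-300
        return -(
            a * np.log(p1 + eps) + b * np.log(1 - p1 + eps)
            + c * np.log(p2 + eps) + d * np.log(1 - p2 + eps)
        )

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(nll, bounds=(-40, 40), method="bounded",
                          options={"xatol": 1e-10})
    return -res.fun


def odds_ratio_2x2(table, conf: float = 0.95, method: str = "profile"):
    """Odds ratio of a 2x2 table with confidence interval.

    ``table`` has rows = exposure (reference level first, exposed second)
    and columns = (events, non-events); the reported odds ratio is the odds
    of an event in the exposed row relative to the reference row,
    ``(c/d) / (a/b)`` for ``[[a, b], [c, d]]``.

    The default confidence interval inverts the profile likelihood of the
    log-odds-ratio (chi-square 1 df cutoff); ``method="wald"`` gives the
    classical normal-approximation interval instead.  Zero cells make the
    point estimate 0 or infinite; the result carries a ``zero_cell`` flag
    and the attainable profile bound is still computed.

    Returns a dict with ``or``, ``ci_low``, ``ci_high``, ``method`` and
    ``zero_cell``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 non-negative integers")
    (a, b), (c, d) = t
    zero = bool((t == 0).any())
    with np.errstate(divide="ignore", invalid="ignore"):
        or_hat = (c * b) / (a * d) if a * d > 0 else np.inf

    alpha = 1.0 - conf
    if method == "wald":
        if zero:
            t = t + 0.5  # Haldane correction for the Wald interval only
            (a, b), (c, d) = t
        from scipy.stats import norm

        log_or = np.log((c * b) / (a * d))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = norm.ppf(1 - alpha / 2)
        lo, hi = np.exp(log_or - z * se), np.exp(log_or + z * se)
        return {"or": float(or_hat), "ci_low": float(lo), "ci_high": float(hi),
                "method": "wald", "zero_cell": zero}

    # profile likelihood interval
    cut = chi2.ppf(conf, 1) / 2.0
    beta_hat = np.log(or_hat) if np.isfinite(or_hat) and or_hat > 0 else None
    ll_grid = lambda bv: _table_loglik(t, bv)
    if beta_hat is None:
        # maximize over a wide grid to locate the (possibly boundary) optimum
        grid = np.linspace(-30, 30, 241)
        vals = [ll_grid(g) for g in grid]
        beta_hat = float(grid[int(np.argmax(vals))])
    ll_max = ll_grid(beta_hat)

    def shifted(bv):
        return ll_grid(bv) - (ll_max - cut)

    def find_bound(direction):
        step, bv = 1.0, beta_hat
        for _ in range(60):
            nxt = bv + direction * step
            if shifted(nxt) < 0:
                return brentq(shifted, min(bv, nxt), max(bv, nxt), xtol=1e-9)
            bv = nxt
            if abs(bv) > 50:
                return direction * np.inf
        return direction * np.inf

    lo = find_bound(-1.0)
    hi = find_bound(+1.0)
    return {
        "or": float(or_hat),
        "ci_low": float(np.exp(lo)) if np.isfinite(lo) else 0.0,
        "ci_high": float(np.exp(hi)) if np.isfinite(hi) else np.inf,
        "method": "profile",
        "zero_cell": zero,
    }


def clopper_pearson(k: int, n: int, conf: float = 0.95):
    """Exact binomial confidence interval via Beta quantiles.

    ``lower = BetaInv(alpha/2; k, n-k+1)`` (0 when k = 0) and
    ``upper = BetaInv(1-alpha/2; k+1, n-k)`` (1 when k = n).
    """
    if not (0 <= k <= n) or n < 1 or int(k) != k or int(n) != n:
        raise ValueError("need integers 0 <= k <= n with n >= 1")
    alpha = 1.0 - conf
    lower = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


# ---------------------------------------------------------------------------
# Freeman-Halton exact test for r x c tables


def _log_table_prob(table, log_row_fact, log_col_fact, log_n_fact):
    return (
        log_row_fact + log_col_fact - log_n_fact
        - gammaln(np.asarray(table, dtype=float) + 1.0).sum()
    )


def _enumerate_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def rec(row_idx, remaining_cols):
        if row_idx == r - 1:
            if all(v >= 0 for v in remaining_cols):
                yield [list(remaining_cols)]
            return
        target = row_sums[row_idx]

        def cells(j, left, acc):
            if j == c - 1:
                if 0 <= left <= remaining_cols[j]:
                    yield acc + [left]
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                yield from cells(j + 1, left - v, acc + [v])

        for row in cells(0, target, []):
            rest = tuple(rc - v for rc, v in zip(remaining_cols, row))
            for tail in rec(row_idx + 1, rest):
                yield [row] + tail

    yield from rec(0, tuple(col_sums))


def fisher_exact_rxc(
    table,
    max_tables: int = 10_000_000,
    monte_carlo: int | None = None,
    seed: int | None = None,
) -> float:
    """Freeman-Halton exact test for an r x c contingency table.

    The p-value is the total probability, under the fixed-margin
    multivariate hypergeometric null, of all tables whose probability does
    not exceed that of the observed table (relative tolerance 1e-7 on the
    comparison).  Tables with a zero row or column margin have a single
    attainable configuration and p = 1.

    Enumeration is exhaustive; if more than ``max_tables`` tables would be
    visited an error suggests the seed-controlled Monte Carlo mode
    (``monte_carlo`` = number of sampled tables, using the independence
    bootstrap over fixed margins via random permutation).
    """
    t = np.asarray(table)
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer) and not np.allclose(
        t, np.round(t)
    ):
        raise ValueError("table must contain non-negative integers")
    t = np.round(t).astype(int)
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        return 1.0
    n = int(t.sum())
    log_row_fact = gammaln(row_sums + 1.0).sum()
    log_col_fact = gammaln(col_sums + 1.0).sum()
    log_n_fact = gammaln(n + 1.0)

    log_p_obs = _log_table_prob(t, log_row_fact, log_col_fact, log_n_fact)
    cutoff = log_p_obs + np.log1p(1e-7)

    if monte_carlo is not None:
        rng = np.random.default_rng(seed)
        rows = np.repeat(np.arange(len(row_sums)), row_sums)
        cols = np.repeat(np.arange(len(col_sums)), col_sums)
        hits = 0
        for _ in range(monte_carlo):
            perm = rng.permutation(cols)
            sim = np.zeros_like(t)
            np.add.at(sim, (rows, perm), 1)
            lp = _log_table_prob(sim, log_row_fact, log_col_fact, log_n_fact)
            if lp <= cutoff:
                hits += 1
        return (hits + 1) / (monte_carlo + 1)

    total = 0.0
    count = 0
    for tab in _enumerate_tables(list(row_sums), list(col_sums)):
        count += 1
        if count > max_tables:
            raise RuntimeError(
                "enumeration budget exceeded; use monte_carlo= with a seed"
            )
        lp = _log_table_prob(tab, log_row_fact, log_col_fact, log_n_fact)
        if lp <= cutoff:
            total += float(np.exp(lp))
    return min(total, 1.0)


def kaplan_meier(time, event) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival estimate.

    Right censoring is honored (``event`` = 0 marks a censored time).
    Returns a step table with columns ``time``, ``survival``, ``at_risk``;
    S(0) = 1 and the estimate is non-increasing.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if (time < 0).any():
        raise ValueError("times must be non-negative")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill()
    return pd.DataFrame(
        {
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
            "at_risk": at_risk.to_numpy(dtype=float),
        }
    )


def cluster_event_summary(labels: pd.Series, events: pd.Series,
                          conf: float = 0.95) -> pd.DataFrame:
    """Per-cluster event counts, proportions and exact binomial CIs.

    Display percentages use half-up rounding to integer percent; the raw
    fractions are kept alongside.
    """
    from decimal import ROUND_HALF_UP, Decimal

    def pct(x):
        return int(Decimal(x * 100).quantize(0, rounding=ROUND_HALF_UP))

    rows = []
    for lab in pd.unique(labels):
        members = labels.index[labels == lab]
        ev = events.reindex(members).dropna().astype(int)
        k, n = int(ev.sum()), int(len(ev))
        lo, hi = clopper_pearson(k, n, conf)
        rows.append(
            {
                "cluster": lab,
                "n": n,
                "events": k,
                "proportion": k / n if n else np.nan,
                "pct": pct(k / n) if n else np.nan,
                "ci_low": lo,
                "ci_high": hi,
                "ci_low_pct": pct(lo),
                "ci_high_pct": pct(hi),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
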