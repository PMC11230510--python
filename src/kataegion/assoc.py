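"""Cohort association statistics: exact 2x2 tests, rank-sum tests, BH-FDR,
and AIC-stepwise generalized linear models for event presence and burden.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_exact_2x2",
    "wilcoxon_rank_sum",
    "bh_fdr",
    "stepwise_glm",
    "StepwiseResult",
]


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns (odds_ratio, p). The p-value sums hypergeometric probabilities of
    all tables (at fixed margins) no more probable than the observed one; the
    odds ratio is the cross-product with a 0.5 continuity correction applied
    when any cell is zero.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if any(x != int(x) for x in (a, b, c, d)):
        raise ValueError("counts must be integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if min(a, b, c, d) == 0:
        oddsr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        oddsr = (a * d) / (b * c)

    n = a + b + c + d
    r1 = a + b  # first row margin
    c1 = a + c  # first column margin
    if n == 0:
        return oddsr, 1.0

    def log_pmf(x: int) -> float:
        return (
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(n - r1 + 1) - math.lgamma(c1 - x + 1)
            - math.lgamma(n - r1 - (c1 - x) + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    p_obs = math.exp(log_pmf(a))
    # relative tolerance mirrors the usual exact-test convention
    p = sum(
        math.exp(lp)
        for x in range(lo, hi + 1)
        if math.exp(lp := log_pmf(x)) <= p_obs * (1 + 1e-7)
    )
    return oddsr, min(p, 1.0)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_below_n: int = 12
) -> tuple[float, float]:
    """Two-sided rank-sum test; exact by enumeration for small samples.

    Returns (rank-sum statistic of ``x``, p). When the combined sample size
    is at most ``exact_below_n`` the p-value enumerates all assignments of
    ranks to the first group; otherwise the normal approximation with tie
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    combined = np.concatenate([x, y])
    order = combined.argsort(kind="mergesort")
    ranks = np.empty_like(combined)
    # midranks for ties
    sorted_vals = combined[order]
    rank_vals = np.arange(1, combined.size + 1, dtype=float)
    i = 0
    while i < combined.size:
        j = i
        while j + 1 < combined.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        rank_vals[i : j + 1] = (i + j + 2) / 2.0
        i = j + 1
    ranks[order] = rank_vals
    w = float(ranks[:nx].sum())

    n = nx + ny
    if n <= exact_below_n:
        # enumerate all ways to pick nx of the n ranks
        sums = [sum(c) for c in itertools.combinations(rank_vals, nx)]
        total = len(sums)
        mean_w = (nx * (n + 1)) / 2.0
        dev = abs(w - mean_w)
        extreme = sum(abs(s - mean_w) >= dev - 1e-9 for s in sums)
        return w, extreme / total
    mean_w = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var_w = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return w, 1.0
    z = (w - mean_w) / math.sqrt(var_w)
    from scipy.stats import norm

    return w, float(2 * norm.sf(abs(z)))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with enforced monotonicity."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class StepwiseResult:
    """Fitted model plus the covariate-selection trace."""

    selected: list[str]
    params: dict[str, float]
    pvalues: dict[str, float]
    ratios: dict[str, float]  # exp(beta): odds ratios / rate ratios
    aic: float
    family: str
    trace: list[dict] = field(default_factory=list)
    excluded_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    n_dropped_incomplete: int = 0
    separation_fallback: bool = False


def _fit(family: str, y: np.ndarray, X: pd.DataFrame):
    import statsmodels.api as sm

    Xc = sm.add_constant(X, has_constant="add")
    if family == "logistic":
        model = sm.Logit(y, Xc)
    elif family == "negative_binomial":
        model = sm.NegativeBinomial(y, Xc)
    else:
        raise ValueError(f"unknown family {family!r}")
    with np.errstate(all="ignore"):
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception as exc:  # noqa: BLE001 - surface the step context upstream
            raise RuntimeError(f"GLM fit failed for covariates {list(X.columns)}: {exc}")
    return res


def _separated(res) -> bool:
    return bool(np.any(~np.isfinite(res.params)) or np.any(np.abs(res.params) > 50))


def stepwise_glm(
    data: pd.DataFrame,
    response: str,
    candidate_covariates: Sequence[str],
    family: str,
    transforms: Mapping[str, str] | None = None,
    corr_cutoff: float = 0.6,
) -> StepwiseResult:
    """Bidirectional AIC-stepwise GLM selection.

    ``family`` is ``"logistic"`` for a binary presence response or
    ``"negative_binomial"`` for a count burden response (dispersion estimated
    by maximum likelihood jointly with the coefficients). Per-covariate
    ``transforms`` map names to ``"log"`` (applied as log1p) or
    ``"identity"``. Rows with missing values in the response or any candidate
    are dropped and counted. Numeric candidates whose pairwise |correlation|
    exceeds ``corr_cutoff`` lose the later-listed member of the pair.
    Separation in a logistic fit triggers an L2-penalized fallback, flagged
    on the result.
    """
    if family not in ("logistic", "negative_binomial"):
        raise ValueError(f"unknown family {family!r}")
    transforms = dict(transforms or {})
    cols = [response, *candidate_covariates]
    df = data[cols].copy()
    n0 = len(df)
    df = df.dropna()
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.info("stepwise_glm: dropped %d incomplete rows", n_dropped)

    for cov, t in transforms.items():
        if t == "log" and cov in df:
            df[cov] = np.log1p(df[cov].astype(float))
        elif t not in ("log", "identity"):
            raise ValueError(f"unknown transform {t!r} for {cov}")

    # encode non-numeric candidates as dummies (drop-first)
    covs: list[str] = []
    for cov in candidate_covariates:
        if pd.api.types.is_numeric_dtype(df[cov]):
            covs.append(cov)
        else:
            dummies = pd.get_dummies(df[cov], prefix=cov, drop_first=True, dtype=float)
            df = pd.concat([df.drop(columns=[cov]), dummies], axis=1)
            covs.extend(dummies.columns)

    # pairwise-correlation exclusion, keeping the earlier-listed covariate
    excluded: list[tuple[str, str, float]] = []
    kept: list[str] = []
    for cov in covs:
        clash = None
        for prev in kept:
            r = float(np.corrcoef(df[cov].astype(float), df[prev].astype(float))[0, 1])
            if abs(r) > corr_cutoff:
                clash = (prev, r)
                break
        if clash:
            excluded.append((cov, clash[0], clash[1]))
            logger.info(
                "stepwise_glm: excluding %s (|corr|=%.2f with %s)", cov, abs(clash[1]), clash[0]
            )
        else:
            kept.append(cov)

    y = df[response].to_numpy(dtype=float)
    trace: list[dict] = []
    selected: list[str] = []
    res = _fit(family, y, df[[]])
    best_aic = float(res.aic)
    trace.append({"action": "start", "covariate": None, "aic": best_aic})

    improved = True
    while improved:
        improved = False
        moves: list[tuple[float, str, str]] = []
        for cov in kept:
            if cov in selected:
                continue
            try:
                r = _fit(family, y, df[selected + [cov]])
            except RuntimeError:
                continue
            moves.append((float(r.aic), "add", cov))
        for cov in selected:
            trial = [c for c in selected if c != cov]
            try:
                r = _fit(family, y, df[trial])
            except RuntimeError:
                continue
            moves.append((float(r.aic), "remove", cov))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1], m[2]))
        aic, action, cov = moves[0]
        if aic < best_aic - 1e-9:
            if action == "add":
                selected.append(cov)
            else:
                selected.remove(cov)
            best_aic = aic
            trace.append({"action": action, "covariate": cov, "aic": aic})
            improved = True

    res = _fit(family, y, df[selected])
    fallback = False
    if family == "logistic" and _separated(res):
        import statsmodels.api as sm

        logger.warning("stepwise_glm: separation detected; penalized fallback")
        Xc = sm.add_constant(df[selected], has_constant="add")
        res = sm.Logit(y, Xc).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        fallback = True

    params = {k: float(v) for k, v in res.params.items()}
    try:
        pvalues = {k: float(v) for k, v in res.pvalues.items()}
    except Exception:  # penalized fits lack standard errors
        pvalues = {}
    ratios = {k: float(np.exp(v)) for k, v in params.items() if k not in ("const", "alpha")}
    return StepwiseResult(
        selected=selected,
        params=params,
        pvalues=pvalues,
        ratios=ratios,
        aic=float(res.aic) if hasattr(res, "aic") else float("nan"),
        family=family,
        trace=trace,
        excluded_correlated=excluded,
        n_dropped_incomplete=n_dropped,
        separation_fallback=fallback,
    )


def prevalence_percent(n_positive: int, n_total: int, decimals: int = 1) -> float:
    """Positive share of a cohort as a rounded percentage."""
    if n_total <= 0 or n_positive < 0 or n_positive > n_total:
        raise ValueError("need 0 <= n_positive <= n_total with n_total > 0")
    return round(100.0 * n_positive / n_total, decimals)
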