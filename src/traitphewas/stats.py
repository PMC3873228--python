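"""2x2 association statistics and auxiliary tests.

Two odds-ratio estimators are exposed because they reproduce different
published conventions:

* ``sample_or_woolf`` — the cross-product sample OR with the Woolf
  (log-scale Wald) confidence interval. This is numerically identical to
  the Wald interval of an unadjusted logistic regression on the 2x2.
* ``fisher_exact`` — the two-sided Fisher exact p-value under the
  point-probability rule, the conditional maximum-likelihood OR under
  the noncentral hypergeometric distribution, and the exact CI obtained
  by inverting one-sided tests at (1-level)/2 per tail. This matches the
  estimate/interval printed by R's ``fisher.test``.

The two are not interchangeable: on moderately sparse tables the exact
CI is wider and the CMLE is pulled toward 1 relative to the sample OR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats as sps

__all__ = [
    "Contingency2x2",
    "OrEstimate",
    "FisherResult",
    "StatsError",
    "sample_or_woolf",
    "fisher_exact",
    "fisher_p",
    "student_t",
    "logistic_fit",
    "bh_fdr",
]

_Z = {0.95: 1.959963984540054}


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class Contingency2x2:
    """Counts (a, b) over the exposed margin and (c, d) over the comparator."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise StatsError(f"negative cell in 2x2: {self}")
            if int(cell) != cell:
                raise StatsError(f"non-integer cell in 2x2: {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def degenerate(self) -> bool:
        """True when a row or column margin is zero."""
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )


@dataclass(frozen=True)
class OrEstimate:
    point: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "woolf"  # woolf | exact_conditional
    continuity_corrected: bool = False
    degenerate: bool = False


def _z(level: float) -> float:
    return _Z.get(level) or float(sps.norm.ppf(0.5 + level / 2))


def sample_or_woolf(table: Contingency2x2, level: float = 0.95) -> OrEstimate:
    """Cross-product odds ratio with the Woolf log-scale Wald interval.

    Any zero cell triggers the Haldane–Anscombe +0.5 correction on all
    four cells, flagged on the result.
    """
    a, b, c, d = (float(x) for x in table.cells())
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half = _z(level) * se
    return OrEstimate(
        point=point,
        ci_low=math.exp(math.log(point) - half),
        ci_high=math.exp(math.log(point) + half),
        level=level,
        method="woolf",
        continuity_corrected=corrected,
    )


# ---------------------------------------------------------------------------
# Fisher exact: p, conditional MLE, exact CI


def _support(table: Contingency2x2) -> tuple[int, int, int, int]:
    """(kmin, kmax, row1 total, col1 total) for the conditional distribution."""
    r1 = table.a + table.b
    r2 = table.c + table.d
    c1 = table.a + table.c
    return max(0, c1 - r2), min(r1, c1), r1, c1


def _log_weights(table: Contingency2x2, log_psi: float) -> tuple[np.ndarray, np.ndarray]:
    """Log noncentral-hypergeometric weights over the conditional support."""
    kmin, kmax, r1, c1 = _support(table)
    r2 = table.c + table.d
    k = np.arange(kmin, kmax + 1)
    logw = (
        special.gammaln(r1 + 1)
        - special.gammaln(k + 1)
        - special.gammaln(r1 - k + 1)
        + special.gammaln(r2 + 1)
        - special.gammaln(c1 - k + 1)
        - special.gammaln(r2 - (c1 - k) + 1)
        + k * log_psi
    )
    return k, logw


def _conditional_mean(table: Contingency2x2, log_psi: float) -> float:
    k, logw = _log_weights(table, log_psi)
    logw -= logw.max()
    w = np.exp(logw)
    return float((k * w).sum() / w.sum())


def _conditional_mle(table: Contingency2x2) -> float:
    kmin, kmax, _, _ = _support(table)
    a = table.a
    if a == kmin:
        return 0.0
    if a == kmax:
        return math.inf
    f = lambda lp: _conditional_mean(table, lp) - a
    lo, hi = -1.0, 1.0
    while f(lo) > 0:
        lo *= 2
        if lo < -500:  # pragma: no cover - guarded by support checks
            return 0.0
    while f(hi) < 0:
        hi *= 2
        if hi > 500:  # pragma: no cover
            return math.inf
    root = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
    return math.exp(root)


def _tail_prob(table: Contingency2x2, log_psi: float, upper: bool) -> float:
    """P(X >= a | psi) when upper, else P(X <= a | psi)."""
    k, logw = _log_weights(table, log_psi)
    logw -= special.logsumexp(logw)
    mask = k >= table.a if upper else k <= table.a
    return float(np.exp(special.logsumexp(logw[mask])))


def _invert_tail(table: Contingency2x2, alpha: float, upper: bool) -> float:
    """Solve for psi where the chosen tail probability equals alpha.

    ``upper=True`` gives the CI lower bound (P(X>=a|psi)=alpha is
    increasing in psi); ``upper=False`` the upper bound.
    """
    f = lambda lp: _tail_prob(table, lp, upper) - alpha
    lo, hi = -1.0, 1.0
    # tail prob is monotone increasing (upper) / decreasing (lower) in psi
    if upper:
        while f(lo) > 0:
            lo *= 2
            if lo < -700:
                return 0.0
        while f(hi) < 0:
            hi *= 2
            if hi > 700:  # pragma: no cover
                return math.inf
    else:
        while f(lo) < 0:
            lo *= 2
            if lo < -700:  # pragma: no cover
                return 0.0
        while f(hi) > 0:
            hi *= 2
            if hi > 700:
                return math.inf
    root = optimize.brentq(f, lo, hi, xtol=1e-10, rtol=1e-10)
    return math.exp(root)


@dataclass(frozen=True)
class FisherResult:
    p: float
    estimate: OrEstimate


def fisher_p(table: Contingency2x2) -> float:
    """Two-sided Fisher exact p only (no estimate; cheaper than the full result)."""
    if table.degenerate:
        return 1.0
    k, logw = _log_weights(table, 0.0)
    logw -= special.logsumexp(logw)
    pmf = np.exp(logw)
    p_obs = pmf[k == table.a][0]
    return min(1.0, float(pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def fisher_exact(table: Contingency2x2, level: float = 0.95) -> FisherResult:
    """Two-sided Fisher exact test with conditional-MLE OR and exact CI.

    The two-sided p sums the central-hypergeometric point probabilities
    of every table (same margins) no more probable than the observed
    one, with a 1+1e-7 relative guard against floating-point ties — the
    convention of R and scipy. Degenerate margins give p=1 and an
    undefined (flagged) OR.
    """
    if table.degenerate:
        return FisherResult(
            p=1.0,
            estimate=OrEstimate(
                point=math.nan, ci_low=math.nan, ci_high=math.nan,
                level=level, method="exact_conditional", degenerate=True,
            ),
        )
    p = fisher_p(table)

    kmin, kmax, _, _ = _support(table)
    alpha = (1 - level) / 2
    point = _conditional_mle(table)
    ci_low = 0.0 if table.a == kmin else _invert_tail(table, alpha, upper=True)
    ci_high = math.inf if table.a == kmax else _invert_tail(table, alpha, upper=False)
    return FisherResult(
        p=p,
        estimate=OrEstimate(
            point=point, ci_low=ci_low, ci_high=ci_high,
            level=level, method="exact_conditional",
        ),
    )


# ---------------------------------------------------------------------------
# auxiliary tests


def student_t(x, y) -> tuple[float, float]:
    """Pooled-variance two-sample Student t, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("each sample needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise StatsError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


@dataclass
class LogisticFit:
    params: np.ndarray
    odds_ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    converged: bool
    separation: bool = False
    pvalues: np.ndarray = field(default_factory=lambda: np.array([]))


def logistic_fit(design: np.ndarray, outcome: np.ndarray,
                 level: float = 0.95) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald intervals.

    ``design`` must include an intercept column. Separation (or an
    all-0/all-1 outcome) is reported through the ``separation`` flag
    rather than raising; point estimates are not meaningful then.
    """
    import statsmodels.api as sm

    design = np.asarray(design, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if outcome.min() == outcome.max():
        return LogisticFit(
            params=np.full(design.shape[1], np.nan),
            odds_ratios=np.full(design.shape[1], np.nan),
            ci_low=np.full(design.shape[1], np.nan),
            ci_high=np.full(design.shape[1], np.nan),
            converged=False, separation=True,
        )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise StatsError("design matrix is rank deficient")
    model = sm.Logit(outcome, design)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=50, tol=1e-8)
        except Exception:
            return LogisticFit(
                params=np.full(design.shape[1], np.nan),
                odds_ratios=np.full(design.shape[1], np.nan),
                ci_low=np.full(design.shape[1], np.nan),
                ci_high=np.full(design.shape[1], np.nan),
                converged=False, separation=True,
            )
    params = np.asarray(res.params, dtype=float)
    separation = bool(np.any(np.abs(params) > 15))
    ci = np.asarray(res.conf_int(alpha=1 - level), dtype=float)
    return LogisticFit(
        params=params,
        odds_ratios=np.exp(params),
        ci_low=np.exp(ci[:, 0]),
        ci_high=np.exp(ci[:, 1]),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation=separation,
        pvalues=np.asarray(res.pvalues, dtype=float),
    )


def bh_fdr(pvalues, q: float = 0.2) -> tuple[np.ndarray, float]:
    """Benjamini–Hochberg step-up over one family of tests.

    Returns per-test significance flags and the threshold line: the
    largest p_(i) with p_(i) <= i*q/m, or 0.0 when none qualifies.
    """
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool), 0.0
    if not np.all(np.isfinite(p)):
        raise StatsError("non-finite p-values in FDR input")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = q * np.arange(1, m + 1) / m
    passing = np.nonzero(ranked <= crit)[0]
    if len(passing) == 0:
        return np.zeros(m, dtype=bool), 0.0
    kstar = passing[-1]
    threshold = float(ranked[kstar])
    flags = np.zeros(m, dtype=bool)
    flags[order[: kstar + 1]] = True
    return flags, threshold
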