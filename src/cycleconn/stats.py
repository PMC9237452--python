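"""Paired condition comparisons with lag-1 autocorrelation handling.

Every metric is compared between conditions on the day-paired differences
(natural − oc, ordered by day index). Two tests are available:

* ``paired_t`` — the classical one-sample t-test on the differences;
* ``gls_ar1_intercept`` — an intercept-only generalized least squares fit
  with AR(1) error correlation, for metrics whose day-ordered differences
  show lag-1 serial structure. (μ, φ, σ) are estimated by exact maximum
  likelihood: the AR(1) covariance is whitened analytically and the
  likelihood concentrated to a 1-D search over φ. Inference uses a t
  reference distribution with n − 1 degrees of freedom.

Effect sizes are pooled-SD Cohen's d (independent-groups formulation, the
convention that matches boxplot-style condition summaries) with a
noncentral-t confidence interval. Familywise error over the k states of one
clustering model is controlled by within-k Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from statsmodels.tsa.stattools import acf as _sm_acf


class StatsError(ValueError):
    pass


@dataclass
class PairedSeries:
    """Day-ordered paired differences (natural − oc) for one metric."""

    days: np.ndarray
    diffs: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.diffs = np.asarray(self.diffs, dtype=float)
        if self.days.shape != self.diffs.shape:
            raise StatsError("days and diffs must align")
        if not np.all(np.diff(self.days) > 0):
            order = np.argsort(self.days, kind="stable")
            self.days = self.days[order]
            self.diffs = self.diffs[order]

    @property
    def n(self) -> int:
        return self.diffs.size


@dataclass
class TestResult:
    """One paired comparison: estimate, CI, test statistic, effect size."""

    estimate: float
    ci_low: float
    ci_high: float
    t_stat: float
    df: float
    p: float
    method: str
    d: float | None = None
    d_ci_low: float | None = None
    d_ci_high: float | None = None
    p_fwer: float | None = None
    phi_hat: float | None = None


def paired_diffs(
    natural: Mapping[int, float],
    oc: Mapping[int, float],
    metric: str = "",
) -> PairedSeries:
    """natural[d] − oc[d] for every paired day d, ordered by day."""
    missing_oc = sorted(set(natural) - set(oc))
    missing_nat = sorted(set(oc) - set(natural))
    if missing_oc or missing_nat:
        raise StatsError(
            f"incomplete pairing: days {missing_oc} missing in oc, "
            f"days {missing_nat} missing in natural"
        )
    days = sorted(natural)
    return PairedSeries(
        days=np.array(days),
        diffs=np.array([natural[d] - oc[d] for d in days]),
        metric=metric,
    )


def paired_t(diffs: PairedSeries, alpha: float = 0.05) -> TestResult:
    """Classical one-sample t-test on the paired differences."""
    x = diffs.diffs
    n = x.size
    if n < 2:
        raise StatsError("need at least 2 paired differences")
    sd = x.std(ddof=1)
    if sd == 0:
        raise StatsError("zero variance in paired differences")
    mean = x.mean()
    se = sd / np.sqrt(n)
    t_stat = mean / se
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t_stat), df))
    tq = sps.t.ppf(1.0 - alpha / 2.0, df)
    return TestResult(
        estimate=float(mean),
        ci_low=float(mean - tq * se),
        ci_high=float(mean + tq * se),
        t_stat=float(t_stat),
        df=df,
        p=max(p, np.finfo(float).tiny),
        method="paired_t",
    )


def pooled_cohens_d(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> tuple[float, float, float]:
    """Pooled-SD Cohen's d for two condition groups, with a noncentral-t CI.

    d = (mean(a) − mean(b)) / s_pooled; for equal group sizes the pooled SD
    reduces to sqrt((s_a² + s_b²)/2). The CI inverts the noncentral-t CDF of
    the observed t = d·sqrt(n_a n_b/(n_a+n_b)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a < 2 or n_b < 2:
        raise StatsError("both groups need n >= 2")
    s2 = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / (n_a + n_b - 2)
    if s2 == 0:
        raise StatsError("zero pooled variance")
    d = float((a.mean() - b.mean()) / np.sqrt(s2))
    scale = np.sqrt(n_a * n_b / (n_a + n_b))
    t_obs = d * scale
    df = n_a + n_b - 2

    def _cdf(nc: float) -> float:
        val = sps.nct.cdf(t_obs, df, nc)
        if np.isnan(val):  # deep-tail underflow; cdf is decreasing in nc
            return 1.0 if nc < t_obs else 0.0
        return float(val)

    def _solve(target_prob: float) -> float:
        # nc such that P(T_{df,nc} <= t_obs) = target_prob
        f = lambda nc: _cdf(nc) - target_prob
        span = abs(t_obs) + 10.0
        lo, hi = t_obs - span, t_obs + span
        while f(lo) < 0:
            lo -= span
        while f(hi) > 0:
            hi += span
        return optimize.brentq(f, lo, hi, xtol=1e-8)

    nc_low = _solve(1.0 - alpha / 2.0)
    nc_high = _solve(alpha / 2.0)
    return d, float(nc_low / scale), float(nc_high / scale)


def acf(diffs: PairedSeries | Sequence[float], max_lag: int) -> np.ndarray:
    """Sample autocorrelations at lags 1..max_lag (biased, mean-subtracted).

    A constant series has no defined autocorrelation; flagged zeros are
    returned with a warning.
    """
    x = diffs.diffs if isinstance(diffs, PairedSeries) else np.asarray(diffs, float)
    if max_lag >= x.size:
        raise StatsError(f"max_lag must be < n={x.size}")
    if x.std() == 0:
        warnings.warn("constant series: autocorrelation undefined, returning zeros",
                      RuntimeWarning, stacklevel=2)
        return np.zeros(max_lag)
    return _sm_acf(x, nlags=max_lag, fft=False)[1:]


def _ar1_whiten(phi: float, y: np.ndarray) -> tuple[float, float, float]:
    """GLS pieces at phi: (hᵀV⁻¹h, μ̂, RSS) via analytic AR(1) whitening.

    Whitening: w₁ = sqrt(1−φ²)·y₁, w_t = y_t − φ·y_{t−1}; same for the
    intercept column h. The GLS mean is the OLS fit of w on h.
    """
    n = y.size
    c = np.sqrt(1.0 - phi * phi)
    w = np.empty(n)
    h = np.empty(n)
    w[0] = c * y[0]
    h[0] = c
    w[1:] = y[1:] - phi * y[:-1]
    h[1:] = 1.0 - phi
    hh = float(h @ h)
    mu = float(h @ w) / hh
    rss = float(np.sum((w - mu * h) ** 2))
    return hh, mu, rss


def _ar1_objective(phi: float, y: np.ndarray, reml: bool) -> float:
    """Concentrated −2·log-likelihood (ML) or −2·restricted LL (REML)."""
    n = y.size
    hh, _, rss = _ar1_whiten(phi, y)
    # log|V| of the AR(1) correlation matrix is −log(1−φ²)
    if reml:
        return (n - 1) * np.log(rss / (n - 1)) + np.log(hh) - np.log(1.0 - phi * phi)
    return n * np.log(rss / n) - np.log(1.0 - phi * phi)


def gls_ar1_intercept(
    diffs: PairedSeries,
    alpha: float = 0.05,
    method: str = "reml",
    bias_correct: bool = True,
    phi_bound: float = 0.99,
) -> TestResult:
    """Intercept-only GLS with AR(1) errors, exact likelihood over (μ, φ, σ).

    Reports the intercept (the mean paired difference adjusted for serial
    correlation), its t statistic against a t(n−1) reference, and the
    estimated lag-1 coefficient ``phi_hat``. φ is estimated by restricted
    maximum likelihood by default (``method="ml"`` for plain ML) and, with
    ``bias_correct``, adjusted by the Kendall–Orcutt-type small-sample term
    (1 + 3φ̂)/n before the standard error is formed. Likelihood estimates of
    φ are biased toward zero at n ≈ 30, which makes the naive plug-in test
    anti-conservative under serial correlation; the corrected plug-in keeps
    the type-I error near the nominal level while vanishing as 1/n, so the
    test still agrees with the classical t-test on white-noise differences
    at large n.
    """
    y = diffs.diffs
    n = y.size
    if n < 4:
        raise StatsError("AR(1) GLS needs at least 4 paired differences")
    if y.std(ddof=1) == 0:
        raise StatsError("zero variance in paired differences")
    if method not in ("reml", "ml"):
        raise StatsError(f"method must be 'reml' or 'ml', got {method!r}")
    reml = method == "reml"
    result = optimize.minimize_scalar(
        lambda phi: _ar1_objective(phi, y, reml),
        bounds=(-phi_bound, phi_bound),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not result.success:
        raise StatsError(f"AR(1) likelihood optimization failed: {result.message}")
    phi = float(result.x)
    if bias_correct:
        phi = min(phi + (1.0 + 3.0 * phi) / n, phi_bound)
    hh, mu, rss = _ar1_whiten(phi, y)
    df = n - 1
    se = np.sqrt((rss / df) / hh)
    t_stat = mu / se
    p = float(2.0 * sps.t.sf(abs(t_stat), df))
    tq = sps.t.ppf(1.0 - alpha / 2.0, df)
    return TestResult(
        estimate=mu,
        ci_low=mu - tq * se,
        ci_high=mu + tq * se,
        t_stat=float(t_stat),
        df=df,
        p=max(p, np.finfo(float).tiny),
        method="gls_ar1",
        phi_hat=phi,
    )


def bonferroni_within_k(pvals: Sequence[float]) -> np.ndarray:
    """p_fwer = min(1, k·p) where k is the number of states in the model."""
    pvals = np.asarray(pvals, dtype=float)
    return np.minimum(1.0, pvals.size * pvals)


def compare_conditions(
    natural: Mapping[int, float],
    oc: Mapping[int, float],
    metric: str = "",
    method: str = "paired_t",
    alpha: float = 0.05,
) -> TestResult:
    """Full paired comparison of one metric: test + pooled effect size."""
    diffs = paired_diffs(natural, oc, metric)
    if method == "paired_t":
        result = paired_t(diffs, alpha)
    elif method == "gls_ar1":
        result = gls_ar1_intercept(diffs, alpha)
    else:
        raise StatsError(f"unknown method {method!r}")
    days = sorted(natural)
    d, d_lo, d_hi = pooled_cohens_d(
        [natural[day] for day in days], [oc[day] for day in days], alpha
    )
    result.d, result.d_ci_low, result.d_ci_high = d, d_lo, d_hi
    return result


def full_test_matrix(
    occupancy_by_k: Mapping[int, pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired test per (k, state) on fractional occurrence, corrected within k.

    ``occupancy_by_k`` maps k to an occupancy table with columns session_id,
    condition, day_index, state_1..state_k (both conditions present for every
    paired day). Returns Σk rows — 209 for the full k ∈ 2..20 sweep.
    """
    rows = []
    for k in sorted(occupancy_by_k):
        occ = occupancy_by_k[k]
        results = []
        for j in range(1, k + 1):
            col = f"state_{j}"
            if col not in occ.columns:
                raise StatsError(f"occupancy table for k={k} lacks column {col}")
            nat = dict(
                zip(
                    occ.loc[occ.condition == "natural", "day_index"],
                    occ.loc[occ.condition == "natural", col],
                )
            )
            oc = dict(
                zip(
                    occ.loc[occ.condition == "oc", "day_index"],
                    occ.loc[occ.condition == "oc", col],
                )
            )
            results.append(compare_conditions(nat, oc, metric=col, alpha=alpha))
        corrected = bonferroni_within_k([r.p for r in results])
        for j, (res, p_fwer) in enumerate(zip(results, corrected), start=1):
            res.p_fwer = float(p_fwer)
            rows.append(
                {
                    "k": k,
                    "state": j,
                    "estimate": res.estimate,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "t": res.t_stat,
                    "df": res.df,
                    "p": res.p,
                    "d": res.d,
                    "d_ci_low": res.d_ci_low,
                    "d_ci_high": res.d_ci_high,
                    "p_fwer": res.p_fwer,
                    "method": res.method,
                }
            )
    return pd.DataFrame(rows)
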