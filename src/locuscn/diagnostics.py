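"""MCMC convergence diagnostics: Heidelberger–Welch stationarity/half-width.

The stationarity test builds a standardized cumulative-sum (Brownian-bridge)
process from the chain and compares its Cramér–von Mises statistic with the
asymptotic null distribution; the leading 10% of the chain is discarded
repeatedly until the test passes or more than half the chain is gone.  The
half-width test then requires the relative precision of the mean —
``z_{1-alpha/2}`` times the spectral-density-based standard error over the
absolute mean — to be at most ``eps``.

The spectral density at frequency zero is estimated from an autoregressive
fit (Yule–Walker coefficients, order selected by AIC).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from statsmodels.regression.linear_model import yule_walker


@dataclass
class HWReport:
    stationarity_passed: bool
    frac_discarded: float
    cvm_stat: float
    cvm_pvalue: float
    halfwidth_passed: bool
    mean: float
    halfwidth: float
    passed: bool


def spectrum0_ar(x: np.ndarray, max_order: int | None = None) -> float:
    """Spectral density of ``x`` at frequency zero via an AR(p) fit.

    ``S(0) = sigma^2 / (1 - sum(phi))^2`` with the order chosen by AIC
    (p = 0 .. max_order, default ``10*log10(n)``).  A chain that is an exact
    linear function of iteration (no residual noise around its trend) has no
    meaningful spectral density; 0 is returned, which downstream turns into
    certain rejection of stationarity.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    v = x.var()
    if v == 0:
        return 0.0
    t = np.arange(n, dtype=float)
    slope = np.cov(t, x, bias=True)[0, 1] / t.var()
    resid = x - x.mean() - slope * (t - t.mean())
    if resid.std() <= 1e-10 * max(1.0, np.abs(x).max()):
        return 0.0
    if max_order is None:
        max_order = int(min(n - 1, 10 * np.log10(n)))
    best_aic, best_s0 = n * np.log(v), v
    for p in range(1, max_order + 1):
        try:
            rho, sigma = yule_walker(x, order=p, method="mle")
        except (np.linalg.LinAlgError, ValueError):
            break
        if sigma <= 0 or not np.isfinite(sigma):
            continue
        aic = n * np.log(sigma**2) + 2.0 * p
        if aic < best_aic:
            denom = 1.0 - rho.sum()
            if abs(denom) < 1e-10:
                continue
            best_aic = aic
            best_s0 = float(sigma**2 / denom**2)
    return best_s0


def cramer_von_mises_cdf(q: float) -> float:
    """CDF of the asymptotic Cramér–von Mises (omega^2) distribution."""
    if q <= 0:
        return 0.0
    if q > 10:
        return 1.0
    total = 0.0
    for k in range(4):
        a = (4 * k + 1) ** 2 / (16.0 * q)
        term = (
            special.gamma(k + 0.5)
            * np.sqrt(4 * k + 1)
            / (special.gamma(k + 1) * np.pi**1.5 * np.sqrt(q))
        )
        # exp(-a) * K_{1/4}(a) computed stably via the scaled Bessel function
        total += term * special.kve(0.25, a) * np.exp(-2.0 * a)
    return float(min(max(total, 0.0), 1.0))


def _cvm_stat(y: np.ndarray, s0: float) -> float:
    """Cramér–von Mises statistic of the Brownian-bridge transform of ``y``."""
    m = y.size
    cs = np.cumsum(y)
    bridge = cs - np.arange(1, m + 1) * y.mean()
    return float((bridge**2).sum() / (m**2 * s0))


def heidelberger_welch(
    chain: np.ndarray, alpha: float = 0.05, eps: float = 0.1
) -> HWReport:
    """Heidelberger–Welch stationarity and half-width diagnostic for one chain.

    A constant chain passes both parts by convention (zero half-width).
    """
    x = np.asarray(chain, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("chain too short for a meaningful diagnostic")

    if np.ptp(x) == 0:
        return HWReport(True, 0.0, 0.0, 1.0, True, float(x[0]), 0.0, True)

    s0 = spectrum0_ar(x[n // 2 :])
    stationary = False
    frac = 0.0
    stat, pval = np.nan, np.nan
    for frac in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        y = x[int(frac * n) :]
        if s0 <= 0:
            # non-constant chain with a degenerate (trend-only) spectrum:
            # the standardized bridge diverges, stationarity cannot hold
            stat, pval = np.inf, 0.0
            continue
        stat = _cvm_stat(y, s0)
        pval = 1.0 - cramer_von_mises_cdf(stat)
        if pval > alpha:
            stationary = True
            break

    if not stationary:
        return HWReport(False, 0.5, stat, pval, False, float(x.mean()), np.nan,
                        False)

    kept = x[int(frac * n) :]
    mean = float(kept.mean())
    s0_kept = spectrum0_ar(kept)
    se = np.sqrt(s0_kept / kept.size)
    halfwidth = float(stats.norm.ppf(1 - alpha / 2) * se)
    if halfwidth == 0.0:
        hw_ok = True
    elif mean == 0.0:
        hw_ok = False
    else:
        hw_ok = halfwidth / abs(mean) <= eps
    return HWReport(True, frac, stat, pval, hw_ok, mean, halfwidth,
                    stationary and hw_ok)
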