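"""Kaplan-Meier estimation and the log-rank statistic.

The log-rank chi-square statistic is the single "distance between survival
curves" used throughout: seed screening, greedy signature growth and the
importance index all call :func:`curve_distance`.  Tail probabilities are
evaluated in log space so that extreme statistics (e.g. 76.6 at 1 df, linear
p ~ 1e-18) still yield a finite ``log10_p``.

Tie convention: censored observations at time t remain at risk for the
events at t.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special

from .datatypes import Dichotomy, KMCurve, LogRankResult, SurvivalData

__all__ = [
    "km_estimate",
    "logrank",
    "curve_distance",
    "chi2_log10_sf",
    "LogRankEngine",
]

_LN10 = math.log(10.0)


def chi2_log10_sf(statistic: float, df: int) -> float:
    """log10 of the chi-square upper-tail probability, finite for any statistic.

    df=1 uses the normal-tail identity p = 2*Phi(-sqrt(x)); df=2 is exactly
    exp(-x/2); larger df fall back to scipy with an asymptotic-series rescue
    if the linear computation underflows.
    """
    if statistic < 0:
        raise ValueError("statistic must be nonnegative")
    if statistic == 0.0:
        return 0.0
    if df == 1:
        return (math.log(2.0) + float(special.log_ndtr(-math.sqrt(statistic)))) / _LN10
    if df == 2:
        return -statistic / (2.0 * _LN10)
    from scipy.stats import chi2

    lp = float(chi2.logsf(statistic, df))
    if not math.isfinite(lp):
        # leading term of the asymptotic expansion of the upper incomplete gamma
        a = df / 2.0
        x = statistic / 2.0
        lp = (a - 1.0) * math.log(x) - x - float(special.gammaln(a))
    return min(lp / _LN10, 0.0)


class LogRankEngine:
    """Precomputed sort/tie structure for repeated log-rank tests on one cohort.

    The greedy search scores thousands of candidate dichotomies against the
    same survival data; precomputing the time ordering and distinct-time
    block boundaries makes each two-group statistic a handful of vectorized
    reductions.
    """

    def __init__(self, surv: SurvivalData):
        time = np.asarray(surv.time, dtype=float)
        event = np.asarray(surv.event, dtype=float)
        order = np.argsort(time, kind="stable")
        self.order = order
        self.time = time[order]
        self.event = event[order]
        self.n = time.size
        self.total_events = float(event.sum())
        self.starts = np.flatnonzero(np.r_[True, np.diff(self.time) > 0])
        self.d = np.add.reduceat(self.event, self.starts)
        self.n_at_risk = self.n - self.starts
        keep = self.d > 0
        self._keep = keep
        self._dk = self.d[keep]
        self._nk = self.n_at_risk[keep].astype(float)
        # per-block hypergeometric variance factor d*(n-d)/(n-1), 0 when n==1
        with np.errstate(divide="ignore", invalid="ignore"):
            vf = self._dk * (self._nk - self._dk) / (self._nk - 1.0)
        self._var_factor = np.where(self._nk > 1.0, vf, 0.0)

    def statistic(self, mask: np.ndarray) -> float:
        """Two-group log-rank chi-square for the boolean group-1 ``mask``.

        ``mask`` is positional over the original (canonical) sample order.
        Returns 0.0 when the variance degenerates.
        """
        if self.total_events == 0:
            raise ValueError("log-rank statistic undefined with no events")
        z = mask[self.order].astype(float)
        d1 = np.add.reduceat(self.event * z, self.starts)[self._keep]
        cz = np.cumsum(z)
        total1 = cz[-1]
        starts = self.starts[self._keep]
        n1 = total1 - np.where(starts > 0, cz[starts - 1], 0.0)
        frac = n1 / self._nk
        o_minus_e = float(np.sum(d1 - self._dk * frac))
        v = float(np.sum(self._var_factor * frac * (1.0 - frac)))
        if v <= 0.0:
            return 0.0
        return o_minus_e * o_minus_e / v

    def statistic_batch(self, masks: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`statistic` over C masks of shape (C, n)."""
        if self.total_events == 0:
            raise ValueError("log-rank statistic undefined with no events")
        z = masks[:, self.order].astype(float)
        d1 = np.add.reduceat(self.event[None, :] * z, self.starts, axis=1)[:, self._keep]
        cz = np.cumsum(z, axis=1)
        starts = self.starts[self._keep]
        prev = np.where(starts > 0, starts - 1, 0)
        n1 = cz[:, -1][:, None] - np.where(starts[None, :] > 0, cz[:, prev], 0.0)
        frac = n1 / self._nk[None, :]
        oe = (d1 - self._dk[None, :] * frac).sum(axis=1)
        v = (self._var_factor[None, :] * frac * (1.0 - frac)).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(v > 0.0, oe * oe / v, 0.0)
        return stat


def km_estimate(surv: SurvivalData, labels: np.ndarray) -> dict[object, KMCurve]:
    """Product-limit estimate per group.

    ``labels`` is any per-sample group assignment; each group must be
    nonempty.  Curves step only at event times; censorings shrink the risk
    set silently.
    """
    labels = np.asarray(labels)
    if labels.shape != (surv.n_samples,):
        raise ValueError("labels length must match the number of samples")
    curves: dict[object, KMCurve] = {}
    for g in np.unique(labels):
        m = labels == g
        if not m.any():
            raise ValueError(f"group {g!r} has zero samples")
        t = surv.time[m]
        e = surv.event[m]
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        n = t.size
        starts = np.flatnonzero(np.r_[True, np.diff(t) > 0])
        d = np.add.reduceat(e.astype(float), starts)
        at_risk = n - starts
        ev = d > 0
        surv_frac = 1.0 - d[ev] / at_risk[ev]
        curves[g] = KMCurve(
            times=t[starts][ev],
            survival=np.cumprod(surv_frac),
            at_risk=at_risk[ev],
            max_followup=float(t[-1]) if n else 0.0,
        )
    return curves


def logrank(surv: SurvivalData, labels: np.ndarray) -> LogRankResult:
    """Classical k-sample log-rank test; df = number of groups - 1.

    For two groups this is the squared standardized O-E score with the
    hypergeometric variance.  Errors if any group is empty or there are no
    events at all.
    """
    labels = np.asarray(labels)
    if labels.shape != (surv.n_samples,):
        raise ValueError("labels length must match the number of samples")
    groups = np.unique(labels)
    g = groups.size
    if g < 2:
        raise ValueError("need at least 2 groups")
    if surv.event.sum() == 0:
        raise ValueError("log-rank statistic undefined with no events")

    if g == 2:
        stat = LogRankEngine(surv).statistic(labels == groups[0])
        return LogRankResult(statistic=stat, log10_p=chi2_log10_sf(stat, 1), df=1)

    # general multi-group form via the (g-1)x(g-1) covariance of O-E
    order = np.argsort(surv.time, kind="stable")
    t = surv.time[order]
    e = surv.event[order].astype(float)
    lab = labels[order]
    n = t.size
    starts = np.flatnonzero(np.r_[True, np.diff(t) > 0])
    d = np.add.reduceat(e, starts)
    n_at = (n - starts).astype(float)
    member = np.stack([(lab == gr).astype(float) for gr in groups], axis=1)  # n x g
    d_k = np.add.reduceat(e[:, None] * member, starts, axis=0)  # blocks x g
    csum = np.cumsum(member, axis=0)
    totals = csum[-1]
    n_k = totals[None, :] - np.where(starts[:, None] > 0, csum[starts - 1], 0.0)
    keep = d > 0
    d, n_at, d_k, n_k = d[keep], n_at[keep], d_k[keep], n_k[keep]
    frac = n_k / n_at[:, None]
    oe = (d_k - d[:, None] * frac).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vfac = np.where(n_at > 1.0, d * (n_at - d) / (n_at - 1.0), 0.0)
    cov = np.einsum("b,bk,bl->kl", vfac, frac, -frac)
    cov[np.diag_indices(g)] += (vfac[:, None] * frac).sum(axis=0)
    v = cov[: g - 1, : g - 1]
    u = oe[: g - 1]
    try:
        stat = float(u @ np.linalg.solve(v, u))
    except np.linalg.LinAlgError:
        stat = float(u @ np.linalg.pinv(v) @ u)
    stat = max(stat, 0.0)
    return LogRankResult(statistic=stat, log10_p=chi2_log10_sf(stat, g - 1), df=g - 1)


def curve_distance(surv: SurvivalData, dichotomy: Dichotomy) -> float:
    """Survival-curve distance between a dichotomy's two groups.

    Defined as the two-group log-rank chi-square statistic; this one
    definition backs seed screening, greedy growth and the importance index.
    """
    if dichotomy.n_samples != surv.n_samples:
        raise ValueError("dichotomy and survival data cover different samples")
    return logrank(surv, dichotomy.assignment).statistic
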