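"""Seed-gene screening: BIC bimodality + k-medians split + log-rank gate.

A gene is a seed candidate when (a) a two-component Gaussian mixture beats a
single Gaussian on BIC, and (b) the two-group k-medians split of its
expression separates survival at the chosen significance level after
multiple-testing correction.

The EM fits run batched across genes (and across the deterministic
quantile-based restarts) so that genome-scale screens stay fast; the
per-gene :func:`bic_bimodality` entry point uses the same arithmetic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    BimodalityResult,
    Dichotomy,
    ExpressionMatrix,
    LogRankResult,
    SeedCandidate,
    SurvivalData,
)
from .survival import LogRankEngine, chi2_log10_sf

__all__ = ["bic_bimodality", "kmedians", "find_seeds", "GaussianMixture1D"]

_LOG_2PI = math.log(2.0 * math.pi)
_N_INITS = 3  # quantile-based deterministic EM restarts


@dataclass(frozen=True)
class GaussianMixture1D:
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    converged: bool


def _single_component_loglik(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Max log-likelihood of one Gaussian (MLE variance)."""
    n = x.shape[axis]
    var = np.var(x, axis=axis)
    return -0.5 * n * (_LOG_2PI + np.log(var) + 1.0)


def _em_batch(
    x: np.ndarray,
    mu: np.ndarray,
    var: np.ndarray,
    w: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
):
    """Two-component 1-D Gaussian EM run in parallel over G problems.

    ``x`` is (G, n); ``mu``/``var``/``w`` are (G, 2).  Returns final
    loglik (G,), converged flags (G,), and the fitted parameters.
    Variances are floored at 1e-6 of each problem's total variance so a
    component cannot collapse onto a single point.
    """
    G, n = x.shape
    var_floor = np.maximum(1e-6 * x.var(axis=1), 1e-12)
    mu = mu.astype(float).copy()
    var = np.maximum(var.astype(float), var_floor[:, None])
    w = w.astype(float).copy()

    loglik = np.full(G, -np.inf)
    converged = np.zeros(G, dtype=bool)
    out_mu, out_var, out_w = mu.copy(), var.copy(), w.copy()

    active = np.arange(G)
    xa, mua, vara, wa, vfa = x, mu, var, w, var_floor
    ll_prev = np.full(G, -np.inf)

    for _ in range(max_iter):
        logp = (
            np.log(wa)[:, :, None]
            - 0.5 * (_LOG_2PI + np.log(vara))[:, :, None]
            - 0.5 * (xa[:, None, :] - mua[:, :, None]) ** 2 / vara[:, :, None]
        )  # (g, 2, n)
        m = logp.max(axis=1)
        lse = m + np.log(np.exp(logp - m[:, None, :]).sum(axis=1))
        ll_new = lse.sum(axis=1)
        resp = np.exp(logp - lse[:, None, :])
        done = np.abs(ll_new - ll_prev) < tol * np.maximum(1.0, np.abs(ll_new))
        if done.any():
            idx = active[done]
            converged[idx] = True
            loglik[idx] = ll_new[done]
            out_mu[idx], out_var[idx], out_w[idx] = mua[done], vara[done], wa[done]
            keep = ~done
            active = active[keep]
            if active.size == 0:
                return loglik, converged, out_mu, out_var, out_w
            xa, mua, vara, wa, vfa = xa[keep], mua[keep], vara[keep], wa[keep], vfa[keep]
            resp, ll_new = resp[keep], ll_new[keep]
        ll_prev = ll_new
        nk = np.maximum(resp.sum(axis=2), 1e-12)
        wa = nk / n
        mua = (resp * xa[:, None, :]).sum(axis=2) / nk
        vara = np.maximum(
            (resp * (xa[:, None, :] - mua[:, :, None]) ** 2).sum(axis=2) / nk,
            vfa[:, None],
        )
    loglik[active] = ll_prev
    out_mu[active], out_var[active], out_w[active] = mua, vara, wa
    return loglik, converged, out_mu, out_var, out_w


def _quantile_inits(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic EM starting points: split at the 50/25/75th percentile.

    Returns (mu, var, w) each of shape (_N_INITS, 2); degenerate splits fall
    back to a symmetric +-1 SD init so the shape is always uniform.
    """
    mus, vars_, ws = [], [], []
    for q in (0.5, 0.25, 0.75):
        cut = float(np.quantile(x, q))
        lo, hi = x[x <= cut], x[x > cut]
        if lo.size < 2 or hi.size < 2:
            s = float(np.std(x))
            mus.append([x.mean() - s, x.mean() + s])
            vars_.append([x.var(), x.var()])
            ws.append([0.5, 0.5])
        else:
            mus.append([lo.mean(), hi.mean()])
            vars_.append([max(lo.var(), 1e-6), max(hi.var(), 1e-6)])
            ws.append([lo.size / x.size, hi.size / x.size])
    return np.array(mus), np.array(vars_), np.array(ws)


def _best_two_component_fit(
    x_batch: np.ndarray, seed: int = 0, n_random_restarts: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best converged two-component loglik per gene.

    ``x_batch`` is (G, n).  Returns (loglik (G,), any_converged (G,),
    component means (G, 2)); non-converged problems carry -inf loglik.
    """
    G, n = x_batch.shape
    inits_mu = np.empty((G, _N_INITS, 2))
    inits_var = np.empty((G, _N_INITS, 2))
    inits_w = np.empty((G, _N_INITS, 2))
    for g in range(G):
        inits_mu[g], inits_var[g], inits_w[g] = _quantile_inits(x_batch[g])

    extra = 0
    if n_random_restarts > 0:
        rng = np.random.default_rng(seed)
        extra = n_random_restarts
        r_mu = np.empty((G, extra, 2))
        for g in range(G):
            for r in range(extra):
                r_mu[g, r] = rng.choice(x_batch[g], size=2, replace=False)
        v = x_batch.var(axis=1)[:, None, None]
        inits_mu = np.concatenate([inits_mu, r_mu], axis=1)
        inits_var = np.concatenate([inits_var, np.broadcast_to(v, r_mu.shape)], axis=1)
        inits_w = np.concatenate([inits_w, np.full_like(r_mu, 0.5)], axis=1)

    n_inits = _N_INITS + extra
    flat_x = np.repeat(x_batch, n_inits, axis=0)
    ll, conv, mu, _, _ = _em_batch(
        flat_x,
        inits_mu.reshape(-1, 2),
        inits_var.reshape(-1, 2),
        inits_w.reshape(-1, 2),
    )
    ll = np.where(conv, ll, -np.inf).reshape(G, n_inits)
    mu = mu.reshape(G, n_inits, 2)
    best = ll.argmax(axis=1)
    rows = np.arange(G)
    return ll[rows, best], conv.reshape(G, n_inits).any(axis=1), mu[rows, best]


def bic_bimodality(values: np.ndarray, seed: int = 0, n_random_restarts: int = 0) -> BimodalityResult:
    """Decide one vs two Gaussian components by BIC (lower is better).

    BIC = -2 lnL + k ln n with k = 2 for the single Gaussian and k = 5 for
    the free-variance two-component mixture.  EM restarts are deterministic
    (quantile-based splits); ``seed`` only feeds the optional random
    restarts.  Constant input is an error; if no EM run converges the gene
    is reported unimodal with a warning.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 8:
        raise ValueError("need at least 8 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite expression values")
    if float(np.var(x)) == 0.0:
        raise ValueError("constant input: bimodality undefined")

    n = x.size
    bic_one = float(-2.0 * _single_component_loglik(x) + 2.0 * math.log(n))
    ll2, any_conv, mu = _best_two_component_fit(x[None, :], seed, n_random_restarts)
    if not any_conv[0]:
        warnings.warn("two-component EM did not converge; reporting unimodal", stacklevel=2)
        return BimodalityResult(is_bimodal=False, bic_one=bic_one, bic_two=np.inf)
    bic_two = float(-2.0 * ll2[0] + 5.0 * math.log(n))
    means = tuple(sorted(float(m) for m in mu[0]))
    return BimodalityResult(
        is_bimodal=bool(bic_two < bic_one),
        bic_one=bic_one,
        bic_two=bic_two,
        component_means=means,
    )


def _bimodality_screen(values: np.ndarray, seed: int = 0) -> np.ndarray:
    """Vectorized BIC bimodality decision per row of a (G, n) matrix.

    Rows with zero variance are reported unimodal (they cannot seed).
    Arithmetic matches :func:`bic_bimodality` exactly.
    """
    G, n = values.shape
    ok = values.var(axis=1) > 0
    out = np.zeros(G, dtype=bool)
    if not ok.any():
        return out
    x = values[ok]
    bic_one = -2.0 * _single_component_loglik(x, axis=1) + 2.0 * math.log(n)
    ll2, any_conv, _ = _best_two_component_fit(x, seed=seed)
    bic_two = np.where(any_conv, -2.0 * ll2 + 5.0 * math.log(n), np.inf)
    out[ok] = bic_two < bic_one
    return out


# ---------------------------------------------------------------------------
# k-medians


def kmedians(points: np.ndarray, k: int = 2, seed: int = 0, max_iter: int = 100) -> np.ndarray:
    """Lloyd-style k-medians: coordinate-wise median centers, L1 assignment.

    Initial centers are the coordinate-wise marginal quantile points (for
    k=2: the 25th and 75th percentiles).  Iterates to label convergence or
    ``max_iter``.  An emptied cluster is re-seeded from the point farthest
    (L1) from the surviving centers, so all k groups end nonempty.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if np.unique(pts, axis=0).shape[0] < k:
        raise ValueError(f"need at least {k} distinct points")
    qs = [(i + 0.5) / k for i in range(k)]  # k=2 -> 0.25, 0.75
    centers = np.stack([np.quantile(pts, q, axis=0) for q in qs])
    labels = np.full(n, -1, dtype=int)
    for _ in range(max_iter):
        dists = np.abs(pts[:, None, :] - centers[None, :, :]).sum(axis=2)
        new_labels = np.argmin(dists, axis=1)
        for c in range(k):
            if not np.any(new_labels == c):
                far = int(np.argmax(dists.min(axis=1)))
                new_labels[far] = c
                centers[c] = pts[far]
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centers[c] = np.median(pts[labels == c], axis=0)
    return labels


def _masked_median(pts: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Median of pts (C, n, d) over the samples selected by mask (C, n).

    Equivalent to np.median on the selected rows; every mask row must select
    at least one sample.  Sort-based so it stays on numpy's fast path.
    """
    srt = np.sort(np.where(mask[:, :, None], pts, np.inf), axis=1)
    cnt = mask.sum(axis=1)
    rows = np.arange(pts.shape[0])
    return 0.5 * (srt[rows, (cnt - 1) // 2, :] + srt[rows, cnt // 2, :])


def _kmedians_batch(
    base: np.ndarray, candidates: np.ndarray, max_iter: int = 100
) -> np.ndarray:
    """Run the k=2 k-medians of (base features + one candidate row) for every
    candidate in parallel.

    ``base`` is (m, n) standardized member expression (may be empty along m);
    ``candidates`` is (C, n).  Returns labels (C, n) identical to calling
    :func:`kmedians` per candidate; candidates that empty a cluster fall back
    to the sequential path to reproduce its re-seeding behavior exactly.
    """
    C, n = candidates.shape
    m = base.shape[0]
    pts = np.empty((C, n, m + 1))
    if m:
        pts[:, :, :m] = base.T[None, :, :]
    pts[:, :, m] = candidates

    centers = np.stack(
        [np.quantile(pts, 0.25, axis=1), np.quantile(pts, 0.75, axis=1)], axis=1
    )  # (C, 2, d)
    labels = np.full((C, n), -1, dtype=int)
    out = np.empty((C, n), dtype=int)
    active = np.arange(C)
    fallback: list[int] = []
    for _ in range(max_iter):
        d0 = np.abs(pts - centers[:, 0, None, :]).sum(axis=2)
        d1 = np.abs(pts - centers[:, 1, None, :]).sum(axis=2)
        new_labels = (d1 < d0).astype(int)
        counts1 = new_labels.sum(axis=1)
        empty = (counts1 == 0) | (counts1 == n)
        if empty.any():
            fallback.extend(active[empty].tolist())
            keep = ~empty
            active = active[keep]
            pts, centers, labels, new_labels = pts[keep], centers[keep], labels[keep], new_labels[keep]
            if active.size == 0:
                break
        done = (new_labels == labels).all(axis=1)
        if done.any():
            out[active[done]] = new_labels[done]
            keep = ~done
            active = active[keep]
            if active.size == 0:
                break
            pts, centers, new_labels = pts[keep], centers[keep], new_labels[keep]
        labels = new_labels
        mask1 = labels.astype(bool)
        centers[:, 0] = _masked_median(pts, ~mask1)
        centers[:, 1] = _masked_median(pts, mask1)
    if active.size:
        out[active] = labels  # hit max_iter: return current assignment
    for c in fallback:
        pt = np.concatenate([base, candidates[c][None, :]], axis=0).T if m else candidates[c][:, None]
        out[c] = kmedians(pt, k=2)
    return out


def find_seeds(
    expr: ExpressionMatrix,
    surv: SurvivalData,
    alpha: float = 0.05,
    correction: str = "bh",
    seed: int = 0,
) -> list[SeedCandidate]:
    """Screen every gene; return seeds passing both gates, best first.

    Per gene: BIC bimodality on its expression across all samples; if
    bimodal, a two-group k-medians split followed by a log-rank test.
    P-values of all tested (bimodal) genes are corrected jointly; candidates
    with adjusted p < ``alpha`` are returned sorted by statistic descending.
    """
    if expr.sample_ids != surv.sample_ids:
        raise ValueError("expression and survival data are not aligned")
    if correction not in {"bh", "bonferroni"}:
        raise ValueError("correction must be 'bh' or 'bonferroni'")
    engine = LogRankEngine(surv)
    bimodal = _bimodality_screen(expr.values, seed=seed)
    idx = np.flatnonzero(bimodal)
    if idx.size == 0:
        return []
    labels_batch = _kmedians_batch(np.empty((0, surv.n_samples)), expr.values[idx])
    tested = []
    for row, labels in zip(idx, labels_batch):
        assignment = labels + 1
        stat = engine.statistic(assignment == 1)
        tested.append(
            (
                expr.probe_ids[row],
                expr.values[row],
                Dichotomy(assignment=assignment),
                stat,
                chi2_log10_sf(stat, 1),
            )
        )
    pvals = np.array([10.0 ** lp for (_, _, _, _, lp) in tested])
    method = "fdr_bh" if correction == "bh" else "bonferroni"
    _, p_adj, _, _ = multipletests(pvals, alpha=alpha, method=method)
    out = []
    for (probe, x, dich, stat, lp), pa in zip(tested, p_adj):
        if pa < alpha:
            out.append(
                SeedCandidate(
                    probe_id=probe,
                    bimodality=bic_bimodality(x, seed=seed),
                    dichotomy=dich,
                    logrank=LogRankResult(statistic=stat, log10_p=lp, df=1),
                    p_adjusted=float(pa),
                )
            )
    out.sort(key=lambda c: (-c.logrank.statistic, c.probe_id))
    return out
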