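"""Greedy signature growth, importance-index pruning and the full pipeline.

Growth starts from a seed gene and, each round, admits the candidate gene
that maximizes the log-rank distance of the k-medians dichotomy computed on
the (robustly standardized) expression of the current members plus the
candidate; it stops when no candidate strictly improves the distance.

Pruning then iteratively removes members that do not significantly
contribute to the separation: a member is dropped while its importance index
(1 minus the distance ratio without/with the gene) falls at or below
``tau``, or while its own expression fails to separate the signature's two
groups (the association gate — a Welch test at a Bonferroni-over-all-probes
level).  The association gate is what keeps greedy survival overfitting out
of the final gene sets: on cohorts with many candidate genes the arg-max
scan reliably finds noise genes whose admission inflates the in-sample
statistic well past the latent-class optimum, yet those genes barely differ
between the two patient groups they supposedly define.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import ttest_ind

from .datatypes import Dichotomy, EnsembleResult, ExpressionMatrix, Signature, SurvivalData
from .seeds import _kmedians_batch, find_seeds, kmedians
from .survival import LogRankEngine, chi2_log10_sf

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "grow_signature",
    "importance_index",
    "prune_signature",
    "run_gsfa",
]


@dataclass(frozen=True)
class SearchConfig:
    """Knobs for seed screening, growth and pruning."""

    alpha: float = 0.05
    correction: str = "bh"
    max_genes: int = 12  # hard cap on signature length
    eps: float = 1e-9  # strict-improvement tolerance on the statistic
    two_dim_growth: bool = False  # score candidates on (seed, candidate) only
    tau: float = 0.0  # prune members with importance <= tau
    assoc_alpha: float | None = 0.05  # association gate level, Bonferroni over all probes
    prune_permutations: int = 0  # optional permutation gate (0 = off)
    prune_perm_alpha: float = 0.05
    stability_threshold: float = 0.8
    seed: int = 0


def _standardize(values: np.ndarray) -> np.ndarray:
    """Per-gene robust scaling: center by median, scale by MAD (fallback 1)."""
    med = np.median(values, axis=1, keepdims=True)
    mad = np.median(np.abs(values - med), axis=1, keepdims=True)
    mad = np.where(mad > 0, mad, 1.0)
    return (values - med) / mad


class _Scorer:
    """Shared machinery: standardized expression + fast log-rank evaluation."""

    def __init__(self, expr: ExpressionMatrix, surv: SurvivalData, config: SearchConfig):
        if expr.sample_ids != surv.sample_ids:
            raise ValueError("expression and survival data are not aligned")
        self.expr = expr
        self.surv = surv
        self.config = config
        self.z = _standardize(expr.values)
        self.engine = LogRankEngine(surv)
        self.index = {p: i for i, p in enumerate(expr.probe_ids)}

    def dichotomize(self, probes: list[str]) -> Dichotomy:
        idx = [self.index[p] for p in probes]
        labels = kmedians(self.z[idx].T, k=2, seed=self.config.seed)
        return Dichotomy(assignment=labels + 1)

    def distance(self, probes: list[str]) -> tuple[float, Dichotomy]:
        d = self.dichotomize(probes)
        return self.engine.statistic(d.assignment == 1), d

    def scan(self, base: list[str], candidates: list[str]) -> np.ndarray:
        """Distance of base+candidate for every candidate, batched."""
        base_z = self.z[[self.index[p] for p in base]] if base else np.empty((0, self.surv.n_samples))
        cand_z = self.z[[self.index[p] for p in candidates]]
        labels = _kmedians_batch(base_z, cand_z)
        return self.engine.statistic_batch(labels == 0)


def grow_signature(
    seed: str,
    expr: ExpressionMatrix,
    surv: SurvivalData,
    config: SearchConfig = SearchConfig(),
    _scorer: "_Scorer | None" = None,
) -> Signature:
    """Greedily grow a signature from ``seed`` until no strict improvement.

    Candidates are scanned in lexicographic probe order so arg-max ties
    resolve to the lowest probe id.  The recorded per-round ``history`` of
    distances is strictly increasing by construction.
    """
    sc = _scorer or _Scorer(expr, surv, config)
    if seed not in sc.index:
        raise KeyError(f"seed probe {seed!r} not found")
    members = [seed]
    try:
        best, dich = sc.distance(members)
    except ValueError as exc:
        raise ValueError(f"cannot score seed {seed!r}: {exc}") from exc
    if not np.any(sc.surv.event[dich.assignment == 1]) or not np.any(
        sc.surv.event[dich.assignment == 2]
    ):
        warnings.warn(
            f"seed {seed!r}: one dichotomy group has no events; returning the bare seed",
            stacklevel=2,
        )
        return Signature(
            seed=seed,
            members=members,
            statistic=best,
            log10_p=chi2_log10_sf(best, 1),
            dichotomy=dich,
            history=[best],
        )
    history = [best]
    candidates = sorted(p for p in sc.index if p != seed)
    while len(members) < config.max_genes and candidates:
        base = [seed] if config.two_dim_growth else members
        stats = sc.scan(base, candidates)
        pick = int(np.argmax(stats))  # first index wins ties = lowest probe id
        if stats[pick] <= best + config.eps:
            break
        chosen = candidates.pop(pick)
        members.append(chosen)
        best, dich = sc.distance(([seed] if config.two_dim_growth else members[:-1]) + [chosen])
        history.append(best)
    if config.two_dim_growth and len(members) > 1:
        # final dichotomy/statistic over the full member set
        best, dich = sc.distance(members)
    return Signature(
        seed=seed,
        members=members,
        statistic=best,
        log10_p=chi2_log10_sf(best, 1),
        dichotomy=dich,
        history=history,
    )


def importance_index(
    sig: Signature,
    gene: str,
    expr: ExpressionMatrix,
    surv: SurvivalData,
    config: SearchConfig = SearchConfig(),
    _scorer: "_Scorer | None" = None,
) -> float:
    """1 - D(members minus gene) / D(members), both recomputed from scratch.

    Always <= 1; negative when removing the gene improves the separation.
    """
    if gene not in sig.members:
        raise KeyError(f"{gene!r} is not a member of the signature")
    if len(sig.members) < 2:
        raise ValueError("cannot remove the only member of a signature")
    sc = _scorer or _Scorer(expr, surv, config)
    d_full, _ = sc.distance(sig.members)
    reduced = [m for m in sig.members if m != gene]
    d_red, _ = sc.distance(reduced)
    if d_full == 0.0:
        return 0.0
    return 1.0 - d_red / d_full


def _all_importances(members: list[str], sc: _Scorer) -> dict[str, float]:
    d_full, _ = sc.distance(members)
    out = {}
    for g in members:
        reduced = [m for m in members if m != g]
        d_red, _ = sc.distance(reduced)
        out[g] = 0.0 if d_full == 0.0 else 1.0 - d_red / d_full
    return out


def _association_log_p(members: list[str], dich: Dichotomy, sc: _Scorer) -> dict[str, float]:
    """Welch-test p (natural log) of each member's expression between the
    signature's two groups."""
    g1 = dich.assignment == 1
    out = {}
    for m in members:
        x = sc.expr.row(m)
        with np.errstate(invalid="ignore"):
            _, p = ttest_ind(x[g1], x[~g1], equal_var=False)
        out[m] = float(np.log(max(p, 1e-300))) if np.isfinite(p) else 0.0
    return out


def _permutation_keeps(gene: str, members: list[str], observed: float, sc: _Scorer) -> bool:
    """Optional gate: keep the gene when its importance beats >= (1-alpha) of
    importances recomputed with that gene's expression randomly permuted."""
    cfg = sc.config
    rng = np.random.default_rng(cfg.seed)
    gi = sc.index[gene]
    original = sc.z[gi].copy()
    exceed = 0
    for _ in range(cfg.prune_permutations):
        sc.z[gi] = rng.permutation(original)
        d_full, _ = sc.distance(members)
        d_red, _ = sc.distance([m for m in members if m != gene])
        perm_imp = 0.0 if d_full == 0.0 else 1.0 - d_red / d_full
        if perm_imp >= observed:
            exceed += 1
    sc.z[gi] = original
    p_emp = (exceed + 1) / (cfg.prune_permutations + 1)
    return p_emp <= cfg.prune_perm_alpha


def prune_signature(
    sig: Signature,
    expr: ExpressionMatrix,
    surv: SurvivalData,
    config: SearchConfig = SearchConfig(),
    _scorer: "_Scorer | None" = None,
) -> Signature:
    """Iteratively remove members that do not significantly contribute.

    A member fails when its importance index is <= ``tau`` or, with the
    association gate enabled, when its expression does not separate the
    current dichotomy's groups at ``assoc_alpha`` / n_probes.  The failing
    member with the smallest importance is removed and everything is
    recomputed; the seed is removable like any other member.  The returned
    signature carries recomputed statistic, dichotomy and importances.
    """
    sc = _scorer or _Scorer(expr, surv, config)
    members = list(sig.members)
    log_gate = (
        np.log(config.assoc_alpha / sc.expr.n_probes) if config.assoc_alpha is not None else None
    )
    while len(members) > 1:
        imps = _all_importances(members, sc)
        _, dich = sc.distance(members)
        failing = {g for g in members if imps[g] <= config.tau}
        if log_gate is not None:
            log_p = _association_log_p(members, dich, sc)
            failing |= {g for g in members if log_p[g] >= log_gate}
        if not failing:
            break
        worst = min(sorted(failing), key=lambda g: imps[g])
        if config.prune_permutations > 0 and _permutation_keeps(worst, members, imps[worst], sc):
            break
        members.remove(worst)
    d, dich = sc.distance(members)
    importance = _all_importances(members, sc) if len(members) > 1 else {members[0]: 1.0}
    return replace(
        sig,
        members=members,
        statistic=d,
        log10_p=chi2_log10_sf(d, 1),
        dichotomy=dich,
        importance=importance,
    )


def run_gsfa(
    expr: ExpressionMatrix,
    surv: SurvivalData,
    config: SearchConfig = SearchConfig(),
) -> EnsembleResult:
    """Full pipeline: seed screening, growth, pruning, ensemble integration.

    Deterministic given ``config``.  Zero seeds yields an empty result with
    every sample classed ``uncertain``.
    """
    from .ensemble import integrate_signatures

    seeds = find_seeds(expr, surv, alpha=config.alpha, correction=config.correction, seed=config.seed)
    logger.info("found %d seed genes", len(seeds))
    if not seeds:
        return EnsembleResult(
            signatures=[],
            dichotomies=[],
            distance_matrix=np.zeros((0, 0)),
            stability=np.array(["uncertain"] * surv.n_samples, dtype=object),
            ranking=None,
            sample_ids=list(surv.sample_ids),
        )
    sc = _Scorer(expr, surv, config)
    signatures = []
    for cand in seeds:
        sig = grow_signature(cand.probe_id, expr, surv, config, _scorer=sc)
        sig = prune_signature(sig, expr, surv, config, _scorer=sc)
        logger.info(
            "seed %s -> %d member(s), statistic %.3f", sig.seed, len(sig.members), sig.statistic
        )
        signatures.append(sig)
    return integrate_signatures(signatures, surv, threshold=config.stability_threshold)
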