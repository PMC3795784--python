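"""Synthetic cohorts with planted signal and recorded ground truth.

A latent binary risk class drives (a) the component membership of planted
bimodal "signature" genes (with per-gene mislabeling, so planted genes carry
complementary information) and (b) a class-dependent exponential hazard.
Decoy genes are bimodal but independent of the class; background genes are
unimodal noise.  Censoring is independent uniform, calibrated to a target
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .datatypes import ExpressionMatrix, SurvivalData

__all__ = ["SimulationConfig", "SyntheticCohort", "simulate_cohort", "realized_censor_fraction"]


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 200
    n_background: int = 500
    n_signature_genes: int = 10
    n_decoy_bimodal: int = 0
    delta: float = 4.0  # mixture-mean separation in within-component SD units
    mislabel_rate: float = 0.1  # per-gene fraction of flipped components
    hazard_ratio: float = 3.0  # class-1 hazard relative to class 0
    baseline_scale: float = 60.0  # mean event time of class 0
    censor_rate: float = 0.3
    weibull_shape: float = 1.0  # 1.0 = exponential
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if min(self.n_background, self.n_signature_genes, self.n_decoy_bimodal) < 0:
            raise ValueError("gene counts must be nonnegative")
        if self.n_background + self.n_signature_genes + self.n_decoy_bimodal == 0:
            raise ValueError("at least one gene required")
        if not 0.0 <= self.mislabel_rate <= 0.5:
            raise ValueError("mislabel_rate must lie in [0, 0.5]")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if self.baseline_scale <= 0:
            raise ValueError("baseline_scale must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")


@dataclass
class SyntheticCohort:
    expr: ExpressionMatrix
    surv: SurvivalData
    latent_class: np.ndarray
    planted_probes: list[str]
    decoy_probes: list[str]
    config: SimulationConfig = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if set(self.planted_probes) & set(self.decoy_probes):
            raise ValueError("planted and decoy probe sets must be disjoint")
        if len(self.latent_class) != self.expr.n_samples:
            raise ValueError("latent class must cover every sample")


def _censor_horizon(config: SimulationConfig, rates: np.ndarray) -> float:
    """Upper bound u of the Uniform(0, u) censoring time so that the expected
    censored fraction matches config.censor_rate (exponential times only)."""

    def expected_censored(u: float) -> float:
        # P(C < T) with C ~ U(0,u), T ~ Exp(rate), averaged over the cohort
        x = rates * u
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-8, 1e6 * config.baseline_scale
    target = config.censor_rate
    return brentq(lambda u: expected_censored(u) - target, lo, hi, xtol=1e-10)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a fully reproducible cohort from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    # balanced latent risk class
    z = np.zeros(n, dtype=int)
    z[rng.permutation(n)[: n // 2]] = 1

    probes: list[str] = []
    rows: list[np.ndarray] = []

    planted = [f"sig{i:04d}" for i in range(config.n_signature_genes)]
    for p in planted:
        comp = z.copy()
        flip = rng.random(n) < config.mislabel_rate
        comp[flip] = 1 - comp[flip]
        rows.append(rng.normal(comp * config.delta, 1.0))
        probes.append(p)

    decoys = [f"dec{i:04d}" for i in range(config.n_decoy_bimodal)]
    for p in decoys:
        comp = rng.integers(0, 2, size=n)
        rows.append(rng.normal(comp * config.delta, 1.0))
        probes.append(p)

    if config.n_background:
        bg = rng.normal(0.0, 1.0, size=(config.n_background, n))
        for i in range(config.n_background):
            probes.append(f"bg{i:05d}")
            rows.append(bg[i])

    sample_ids = [f"S{i:04d}" for i in range(n)]
    expr = ExpressionMatrix(probes, sample_ids, np.vstack(rows))

    # event times: class-1 hazard = hazard_ratio * class-0 hazard
    base_rate = 1.0 / config.baseline_scale
    rates = np.where(z == 1, base_rate * config.hazard_ratio, base_rate)
    u = rng.random(n)
    if config.weibull_shape == 1.0:
        t_event = -np.log(u) / rates
    else:
        t_event = (-np.log(u)) ** (1.0 / config.weibull_shape) / rates
    if config.censor_rate > 0:
        # calibration assumes exponential times; adequate for shapes near 1
        horizon = _censor_horizon(config, rates)
        t_cens = rng.uniform(0.0, horizon, size=n)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(n, dtype=int)
        time = t_event
    surv = SurvivalData(sample_ids, time, event)
    return SyntheticCohort(
        expr=expr,
        surv=surv,
        latent_class=z,
        planted_probes=planted,
        decoy_probes=decoys,
        config=config,
    )


def realized_censor_fraction(cohort: SyntheticCohort) -> float:
    """Observed fraction of censored samples."""
    return float(np.mean(cohort.surv.event == 0))
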