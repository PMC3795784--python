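"""Core value objects shared across the pipeline.

All containers validate their invariants on construction.  Sample order is
canonical (lexicographic over sample id) once :func:`survsig.io.align` has
been applied; every per-sample vector downstream (dichotomy assignments,
stability classes) is positional over that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "SurvivalData",
    "Dichotomy",
    "LogRankResult",
    "KMCurve",
    "BimodalityResult",
    "SeedCandidate",
    "Signature",
    "GeneRanking",
    "EnsembleResult",
]


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Genes-by-samples matrix of finite log-scale intensities."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if self.values.size == 0:
            raise ValueError("empty expression matrix")
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            bad = int(np.count_nonzero(~np.isfinite(self.values)))
            raise ValueError(f"expression matrix contains {bad} non-finite values")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self, probe_id: str) -> int:
        try:
            return self.probe_ids.index(probe_id)
        except ValueError:
            raise KeyError(f"probe {probe_id!r} not found") from None

    def row(self, probe_id: str) -> np.ndarray:
        return self.values[self.probe_index(probe_id)]

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.probe_index(p) for p in probe_ids]
        return ExpressionMatrix(list(probe_ids), list(self.sample_ids), self.values[idx])


@dataclass
class SurvivalData:
    """Per-sample follow-up time (any consistent unit) and event indicator."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length must match sample_ids")
        _check_unique(self.sample_ids, "sample")
        if n == 0:
            raise ValueError("empty survival table")
        if not np.all(np.isfinite(self.time)):
            raise ValueError("non-finite follow-up time")
        if np.any(self.time < 0):
            raise ValueError("negative follow-up time")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicator must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class Dichotomy:
    """Two-group sample partition with an optional prognosis orientation.

    ``assignment`` holds group codes in {1, 2}, positional over the canonical
    sample order.  ``orientation`` maps each group code to ``"good"`` or
    ``"poor"`` once :func:`survsig.ensemble.orient_dichotomy` has run.
    """

    assignment: np.ndarray
    orientation: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.ndim != 1 or self.assignment.size < 2:
            raise ValueError("assignment must be a vector of >= 2 samples")
        codes = set(np.unique(self.assignment).tolist())
        if codes != {1, 2}:
            raise ValueError(f"assignment must use both group codes 1 and 2, got {codes}")
        if self.orientation is not None:
            if set(self.orientation) != {1, 2} or set(self.orientation.values()) != {"good", "poor"}:
                raise ValueError("orientation must map {1,2} onto {'good','poor'}")

    @property
    def n_samples(self) -> int:
        return int(self.assignment.size)

    @property
    def is_oriented(self) -> bool:
        return self.orientation is not None

    def group_mask(self, code: int) -> np.ndarray:
        return self.assignment == code

    def prognosis_labels(self) -> np.ndarray:
        """Per-sample 'good'/'poor' labels; requires orientation."""
        if self.orientation is None:
            raise ValueError("dichotomy is not oriented")
        out = np.empty(self.assignment.size, dtype=object)
        for code, label in self.orientation.items():
            out[self.assignment == code] = label
        return out


@dataclass(frozen=True)
class LogRankResult:
    """Log-rank chi-square statistic with its tail probability in log10 space.

    ``log10_p`` stays finite even when the linear-scale p-value underflows;
    report layers print ``<-16`` below machine precision.
    """

    statistic: float
    log10_p: float
    df: int

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("log-rank statistic must be nonnegative")
        if self.log10_p > 1e-12:
            raise ValueError("log10 p-value must be <= 0")
        if self.df < 1:
            raise ValueError("df must be >= 1")

    @property
    def p_value(self) -> float:
        """Linear-scale p (may underflow to 0.0 for extreme statistics)."""
        return float(10.0 ** self.log10_p)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve for one group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    max_followup: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "survival", np.asarray(self.survival, dtype=float))
        object.__setattr__(self, "at_risk", np.asarray(self.at_risk, dtype=int))
        if not (len(self.times) == len(self.survival) == len(self.at_risk)):
            raise ValueError("curve arrays must share a length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be nonincreasing")

    def survival_at(self, t: float) -> float:
        """Step-function evaluation S(t)."""
        idx = int(np.searchsorted(self.times, t, side="right"))
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def restricted_mean(self, tau: float) -> float:
        """Area under the step curve from 0 to ``tau``."""
        if tau <= 0:
            return 0.0
        knots = np.concatenate(([0.0], self.times[self.times < tau], [tau]))
        heights = np.concatenate(([1.0], self.survival[self.times < tau]))
        return float(np.sum(np.diff(knots) * heights))


@dataclass(frozen=True)
class BimodalityResult:
    is_bimodal: bool
    bic_one: float
    bic_two: float
    component_means: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        # lower BIC is better under the -2 lnL + k ln n convention
        if self.is_bimodal != (self.bic_two < self.bic_one):
            raise ValueError("is_bimodal must equal bic_two < bic_one")


@dataclass
class SeedCandidate:
    probe_id: str
    bimodality: BimodalityResult
    dichotomy: Dichotomy
    logrank: LogRankResult
    p_adjusted: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_adjusted <= 1.0):
            raise ValueError("adjusted p must lie in [0,1]")


@dataclass
class Signature:
    """A grown (and possibly pruned) gene set with its induced dichotomy.

    ``members`` is in inclusion order; the seed may have been pruned away.
    """

    seed: str
    members: list[str]
    statistic: float
    log10_p: float
    dichotomy: Dichotomy
    importance: dict[str, float] = field(default_factory=dict)
    history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("signature must have at least one member")
        if self.importance and set(self.importance) != set(self.members):
            raise ValueError("importance must be defined for exactly the members")


@dataclass(frozen=True)
class GeneRanking:
    """Genes scored by signature occurrence count and mean importance."""

    probe_ids: tuple[str, ...]
    n_signatures: tuple[int, ...]
    mean_importance: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.probe_ids) == len(self.n_signatures) == len(self.mean_importance)):
            raise ValueError("ranking columns must share a length")
        if any(n < 1 for n in self.n_signatures):
            raise ValueError("every ranked gene must occur in >= 1 signature")


@dataclass
class EnsembleResult:
    signatures: list[Signature]
    dichotomies: list[Dichotomy]
    distance_matrix: np.ndarray
    stability: np.ndarray  # per-sample: 'stable_good' | 'stable_poor' | 'uncertain'
    ranking: GeneRanking | None
    sample_ids: list[str]
    linkage: np.ndarray | None = None  # scipy linkage over dichotomies (K >= 2)

    def __post_init__(self) -> None:
        k = len(self.signatures)
        if len(self.dichotomies) != k:
            raise ValueError("one oriented dichotomy per signature required")
        if k:
            dm = np.asarray(self.distance_matrix, dtype=float)
            if dm.shape != (k, k):
                raise ValueError("distance matrix shape must be KxK")
            if not np.allclose(dm, dm.T) or not np.allclose(np.diag(dm), 0.0):
                raise ValueError("distance matrix must be symmetric with zero diagonal")
            self.distance_matrix = dm
        if len(self.stability) != len(self.sample_ids):
            raise ValueError("stability must cover every sample")

    @property
    def n_signatures(self) -> int:
        return len(self.signatures)
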