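"""Deterministic and probabilistic sensitivity analysis.

One-way analysis moves a single parameter to each end of its plausible range
(co-varying its complement partner, if any, so branch probabilities keep
summing to one) and records the societal incremental cost at both endpoints;
the tornado ranks parameters by the swing between endpoints.

The probabilistic analysis draws all uncertain parameters jointly from
method-of-moments distributions — beta for probabilities, gamma for costs —
anchored at the base-case value with standard deviation (range width)/4,
i.e. the stated range is read as roughly a ±2 sd interval.  Each of the
seeded Monte Carlo draws re-evaluates the societal incremental cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .costing import HEALTHCARE, SOCIETAL, CostAxis
from .model import CmaModel, EvaluationResult, evaluate

__all__ = [
    "TornadoEntry",
    "PsaConfig",
    "PsaResult",
    "BetaDist",
    "GammaDist",
    "PointMass",
    "one_way",
    "tornado",
    "scenario_healthcare",
    "fit_beta",
    "fit_gamma",
    "run_psa",
    "beta_from_mean_sd",
]


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    """Incremental cost at both ends of one parameter's range."""

    parameter_id: str
    low: float
    high: float
    incremental_at_low: float
    incremental_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.incremental_at_high - self.incremental_at_low)


def _incremental_at(
    model: CmaModel,
    prob_overrides: dict[str, float] | None = None,
    cost_overrides: dict[str, float] | None = None,
) -> float:
    return evaluate(
        model, SOCIETAL, prob_overrides=prob_overrides, cost_overrides=cost_overrides
    ).incremental


def _probability_overrides(model: CmaModel, pid: str, value: float) -> dict[str, float]:
    """Set one probability, co-varying its complement partner.

    At an endpoint of 1.0 the partner is clamped to 0 (the sibling branch is
    annihilated).
    """
    overrides = {pid: value}
    param = model.params[pid]
    if param.complement_group is not None:
        for other_id, other in model.params.items():
            if other_id != pid and other.complement_group == param.complement_group:
                overrides[other_id] = max(0.0, 1.0 - value)
    return overrides


def _cost_axes(model: CmaModel) -> dict[str, CostAxis]:
    return {axis.id: axis for axis in model.costbook.axes()}


def one_way(
    model: CmaModel,
    parameter_id: str,
    range: tuple[float, float] | None = None,
) -> TornadoEntry:
    """Societal incremental cost at both ends of one parameter's range.

    ``parameter_id`` names either a probability parameter or a cost axis
    (a component id or a grouped bundle id); all other parameters stay at
    base.  ``range`` overrides the stored range.
    """
    if parameter_id in model.params:
        param = model.params[parameter_id]
        rng = range if range is not None else param.range
        if rng is None:
            raise ValueError(f"probability parameter {parameter_id!r} has no range")
        low, high = float(rng[0]), float(rng[1])
        if not (0.0 <= low <= high <= 1.0):
            raise ValueError(
                f"probability range [{low}, {high}] for {parameter_id!r} outside [0, 1]"
            )
        inc_low = _incremental_at(model, _probability_overrides(model, parameter_id, low))
        inc_high = _incremental_at(model, _probability_overrides(model, parameter_id, high))
        return TornadoEntry(parameter_id, low, high, inc_low, inc_high)

    axes = _cost_axes(model)
    if parameter_id not in axes:
        raise KeyError(
            f"{parameter_id!r} is neither a probability parameter nor a cost axis"
        )
    axis = axes[parameter_id]
    rng = range if range is not None else axis.range
    if rng is None:
        raise ValueError(f"cost axis {parameter_id!r} has no range")
    low, high = float(rng[0]), float(rng[1])
    inc_low = _incremental_at(model, cost_overrides={parameter_id: low})
    inc_high = _incremental_at(model, cost_overrides={parameter_id: high})
    return TornadoEntry(parameter_id, low, high, inc_low, inc_high)


def tornado(
    model: CmaModel,
    parameter_ids: list[str] | None = None,
) -> list[TornadoEntry]:
    """One-way analyses for every ranged parameter, sorted by swing (descending).

    Both members of a complement group describe the same uncertainty axis
    (the one-way analysis co-varies them), so by default one entry per group
    is produced, keyed by the group's first-declared member; stable sort
    preserves declaration order among ties.
    """
    if parameter_ids is None:
        parameter_ids = []
        seen_groups: set[str] = set()
        for pid, param in model.params.items():
            if param.range is None:
                continue
            if param.complement_group is not None:
                if param.complement_group in seen_groups:
                    continue
                seen_groups.add(param.complement_group)
            parameter_ids.append(pid)
        for axis in model.costbook.axes():
            if axis.range is not None:
                parameter_ids.append(axis.id)
    entries = [one_way(model, pid) for pid in parameter_ids]
    return sorted(entries, key=lambda e: -e.swing)


def scenario_healthcare(model: CmaModel) -> EvaluationResult:
    """Re-evaluate under the healthcare-sector perspective.

    Patient-borne time and transport components are excluded; only tariffs
    and the GP's scanning add-on remain.
    """
    return evaluate(model, HEALTHCARE)


# ---------------------------------------------------------------------------
# Parameter distributions (method of moments)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BetaDist:
    alpha: float
    beta: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.beta(self.alpha, self.beta, size=n)


@dataclass(frozen=True)
class GammaDist:
    shape: float
    scale: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.gamma(self.shape, self.scale, size=n)


@dataclass(frozen=True)
class PointMass:
    """Degenerate distribution: a parameter with no uncertainty."""

    value: float

    @property
    def mean(self) -> float:
        return self.value

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, self.value)


def beta_from_mean_sd(mean: float, sd: float) -> BetaDist | PointMass:
    """Method-of-moments beta: alpha = m(m(1−m)/v − 1), beta = alpha(1−m)/m."""
    if not (0.0 < mean < 1.0):
        raise ValueError(f"beta mean must be in (0, 1); got {mean}")
    if sd == 0.0:
        return PointMass(mean)
    v = sd * sd
    if v >= mean * (1.0 - mean):
        raise ValueError(
            f"variance {v:.6g} >= m(1-m) = {mean * (1 - mean):.6g}: no beta "
            "distribution has these moments; narrow the range"
        )
    alpha = mean * (mean * (1.0 - mean) / v - 1.0)
    beta = alpha * (1.0 - mean) / mean
    return BetaDist(alpha=alpha, beta=beta)


def fit_beta(mean: float, range: tuple[float, float]) -> BetaDist | PointMass:
    """Beta distribution for a probability: mean preserved, sd = (high − low)/4."""
    low, high = float(range[0]), float(range[1])
    if low > high:
        raise ValueError(f"range low {low} > high {high}")
    return beta_from_mean_sd(mean, (high - low) / 4.0)


def fit_gamma(mean: float, range: tuple[float, float]) -> GammaDist | PointMass:
    """Gamma distribution for a cost: shape = m²/v, scale = v/m, sd = width/4."""
    if mean <= 0:
        raise ValueError(f"gamma mean must be > 0; got {mean}")
    low, high = float(range[0]), float(range[1])
    if low > high:
        raise ValueError(f"range low {low} > high {high}")
    sd = (high - low) / 4.0
    if sd == 0.0:
        return PointMass(mean)
    v = sd * sd
    return GammaDist(shape=mean * mean / v, scale=v / mean)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsaConfig:
    """Monte Carlo settings.

    ``excluded_ids`` holds parameters fixed at base.  Unit prices are never
    sampled as such — per-visit component costs are the sampled quantities —
    so the three unit costs held fixed in the reference analysis (mileage,
    GP scanning time, patient time) are excluded structurally; ids listed
    here additionally pin any probability parameter or cost axis.
    """

    n_draws: int = 10_000
    seed: int = 0
    excluded_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        object.__setattr__(self, "excluded_ids", tuple(self.excluded_ids))


@dataclass(frozen=True)
class PsaResult:
    """Monte Carlo incremental-cost draws with summary statistics (€)."""

    draws: np.ndarray
    mean: float
    sd: float
    p2_5: float
    p97_5: float
    fraction_cost_saving: float
    n_draws: int
    seed: int

    @staticmethod
    def from_draws(draws: np.ndarray, seed: int) -> "PsaResult":
        draws = np.asarray(draws, dtype=float)
        return PsaResult(
            draws=draws,
            mean=float(np.mean(draws)),
            sd=float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0,
            p2_5=float(np.percentile(draws, 2.5)),
            p97_5=float(np.percentile(draws, 97.5)),
            fraction_cost_saving=float(np.mean(draws < 0.0)),
            n_draws=int(draws.size),
            seed=seed,
        )


def _psa_distributions(
    model: CmaModel, config: PsaConfig
) -> tuple[list[tuple[str, object]], list[tuple[str, object]]]:
    """Fit sampling distributions in declaration order.

    Probabilities: one beta per complement group (first-declared member is
    sampled, the partner set to its complement) plus ungrouped parameters.
    Costs: one gamma per ranged axis.  Excluded or rangeless parameters are
    held at base and omitted.
    """
    prob_dists: list[tuple[str, object]] = []
    seen_groups: set[str] = set()
    for pid, param in model.params.items():
        if param.complement_group is not None:
            if param.complement_group in seen_groups:
                continue
            seen_groups.add(param.complement_group)
        if not param.psa_included or pid in config.excluded_ids:
            continue
        if param.range is None or param.range[0] == param.range[1]:
            continue
        prob_dists.append((pid, fit_beta(param.base, param.range)))

    cost_dists: list[tuple[str, object]] = []
    for axis in model.costbook.axes():
        if not axis.psa_included or axis.id in config.excluded_ids:
            continue
        if axis.range is None or axis.range[0] == axis.range[1]:
            continue
        cost_dists.append((axis.id, fit_gamma(axis.base, axis.range)))
    return prob_dists, cost_dists


def run_psa(model: CmaModel, config: PsaConfig) -> PsaResult:
    """Seeded second-order Monte Carlo over parameter uncertainty.

    Parameters are drawn independently (complement partners aside); each
    joint draw re-evaluates the societal incremental cost.  Identical
    configurations give bitwise-identical results.
    """
    prob_dists, cost_dists = _psa_distributions(model, config)
    rng = np.random.default_rng(config.seed)
    n = config.n_draws

    prob_samples = {pid: dist.sample(rng, n) for pid, dist in prob_dists}
    cost_samples = {aid: dist.sample(rng, n) for aid, dist in cost_dists}

    partners: dict[str, str] = {}
    for pid, _ in prob_dists:
        group = model.params[pid].complement_group
        if group is not None:
            for other_id, other in model.params.items():
                if other_id != pid and other.complement_group == group:
                    partners[pid] = other_id

    draws = np.empty(n)
    for i in range(n):
        prob_overrides: dict[str, float] = {}
        for pid, samples in prob_samples.items():
            p = float(samples[i])
            prob_overrides[pid] = p
            if pid in partners:
                prob_overrides[partners[pid]] = max(0.0, 1.0 - p)
        cost_overrides = {aid: float(s[i]) for aid, s in cost_samples.items()}
        draws[i] = _incremental_at(model, prob_overrides, cost_overrides)
    return PsaResult.from_draws(draws, seed=config.seed)
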