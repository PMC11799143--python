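"""Anchoring-and-adjustment simulation of speeded proportion judgments.

The model treats a binary perceptual judgment — "do black tiles make up more
than 50% of a grid whose true black proportion is ``c_prop``?" — as a
Metropolis–Hastings (MH) chain of small adjustments.  An estimate ``v_t`` of
the black proportion starts at an anchor drawn from a prior centred on 0.5
and is nudged ``n_steps`` times by Gaussian proposals; a proposal is accepted
by the MH rule under a target density N(``c_prop``, ``belief_sd``) truncated
to [0, 1].  A chain is "correct" at time ``t`` if ``v_t > 0.5`` (all
simulated conditions have ``c_prop > 0.5``).

Averaging correctness over many chains gives an accuracy curve (the thinking
*benefit*), rescaled so its maximum is 1.  Subtracting a linear thinking
*cost* schedule — 0 at ``t = 0``, ``max_cost`` at ``t = n_steps`` — gives the
*total benefit*.  With ``max_cost = 0`` the total benefit is the accuracy
curve itself (the classical speed–accuracy trade-off regime, SAT); with a
positive ``max_cost`` the curve peaks early and then declines (the
resource-rational regime).  The per-individual peak time of the total
benefit, aggregated over a population of simulated individuals, is the
model's headline statistic: resource-rational peaks are earlier and in a
narrower range than SAT peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimulationConfig",
    "BenefitCurves",
    "PeakSummary",
    "truncated_normal_density",
    "sample_prior",
    "acceptance_probability",
    "mh_step",
    "run_chains",
    "benefit_curves",
    "peak_time",
    "simulate_population",
    "compare_cost_regimes",
]


class DegenerateCurveError(ValueError):
    """Raised when an accuracy curve is identically zero and cannot be rescaled."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation arm.

    Parameters
    ----------
    c_prop : float
        True black proportion of the stimulus; the target density is centred
        here.  0.55 is the difficult condition, 0.65 the easy one.
    belief_sd : float
        Spread ``b`` of both the prior (around 0.5) and the target density —
        the strength of belief.
    proposal_sd : float
        Standard deviation of the Gaussian adjustment proposal.
    n_steps : int
        Number of adjustments ``T`` per chain.
    n_iterations : int
        Chains per simulated individual (trial-to-trial variability).
    n_individuals : int
        Population size for peak-time statistics.
    max_cost : float
        Thinking cost at ``t = n_steps``; the cost rises linearly from 0.
        0.0 selects the SAT regime, positive values the resource-rational
        regime.
    prior : {"unimodal", "bimodal"}
        Anchor distribution: N(0.5, belief_sd) truncated to [0, 1], or an
        equal-weight mixture of truncated normals at ``bimodal_means``.
    seed : int
        Root seed; individual ``i`` uses the stream
        ``SeedSequence(entropy=seed, spawn_key=(i,))`` so populations can be
        extended without reshuffling earlier individuals.
    """

    c_prop: float = 0.55
    belief_sd: float = 0.1
    proposal_sd: float = 0.05
    n_steps: int = 150
    n_iterations: int = 1000
    n_individuals: int = 500
    max_cost: float = 0.0
    prior: Literal["unimodal", "bimodal"] = "unimodal"
    bimodal_means: tuple[float, float] = (0.4, 0.6)
    bimodal_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.c_prop < 1.0:
            raise ValueError(f"c_prop must be in (0, 1), got {self.c_prop}")
        if self.belief_sd <= 0 or self.proposal_sd <= 0 or self.bimodal_sd <= 0:
            raise ValueError("belief_sd, proposal_sd and bimodal_sd must be positive")
        if self.max_cost < 0:
            raise ValueError(f"max_cost must be non-negative, got {self.max_cost}")
        if self.n_steps < 1 or self.n_iterations < 1 or self.n_individuals < 1:
            raise ValueError("n_steps, n_iterations and n_individuals must be >= 1")
        if self.prior not in ("unimodal", "bimodal"):
            raise ValueError(f"prior must be 'unimodal' or 'bimodal', got {self.prior!r}")
        if not all(0.0 < m < 1.0 for m in self.bimodal_means):
            raise ValueError("bimodal_means must lie in (0, 1)")

    @property
    def condition_label(self) -> str:
        return (
            f"c_prop={self.c_prop:g}, max_cost={self.max_cost:g}, prior={self.prior}"
        )

    def rng_for_individual(self, index: int) -> np.random.Generator:
        """Independent, reproducible stream for one simulated individual."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(index,))
        )


def truncated_normal_density(
    x,
    mean: float,
    sd: float,
    lo: float = 0.0,
    hi: float = 1.0,
):
    """Density of N(mean, sd) truncated to [lo, hi]; exactly 0 outside.

    Vectorized over ``x``.  Scalars in, scalar out.
    """
    if sd <= 0:
        raise ValueError(f"sd must be positive, got {sd}")
    if lo >= hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    x = np.asarray(x, dtype=float)
    z = stats.norm.cdf(hi, mean, sd) - stats.norm.cdf(lo, mean, sd)
    inside = (x >= lo) & (x <= hi)
    dens = np.where(inside, stats.norm.pdf(x, mean, sd) / z, 0.0)
    return dens if dens.ndim else float(dens)


def sample_prior(
    config: SimulationConfig,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw initial anchors from the configured prior, truncated to [0, 1]."""
    n = 1 if size is None else size
    b = config.belief_sd
    if config.prior == "unimodal":
        a, bnd = (0.0 - 0.5) / b, (1.0 - 0.5) / b
        draws = stats.truncnorm.rvs(a, bnd, loc=0.5, scale=b, size=n, random_state=rng)
    else:
        m1, m2 = config.bimodal_means
        s = config.bimodal_sd
        pick = rng.random(n) < 0.5
        means = np.where(pick, m1, m2)
        # componentwise truncated draws; bounds are in each component's own units
        draws = stats.truncnorm.rvs(
            (0.0 - means) / s, (1.0 - means) / s, loc=means, scale=s, random_state=rng
        )
    return float(draws[0]) if size is None else np.asarray(draws)


def acceptance_probability(
    v_prev,
    proposal,
    c_prop: float,
    belief_sd: float,
):
    """MH acceptance probability for moving from ``v_prev`` to ``proposal``.

    The target is N(c_prop, belief_sd) truncated to [0, 1]; truncation
    renormalization cancels in the ratio, so inside the support the ratio is
    the plain Gaussian density ratio, and proposals outside [0, 1] have zero
    density and are never accepted.
    """
    v_prev = np.asarray(v_prev, dtype=float)
    proposal = np.asarray(proposal, dtype=float)
    inside = (proposal >= 0.0) & (proposal <= 1.0)
    log_ratio = ((v_prev - c_prop) ** 2 - (proposal - c_prop) ** 2) / (
        2.0 * belief_sd**2
    )
    prob = np.where(inside, np.minimum(1.0, np.exp(np.minimum(log_ratio, 0.0))), 0.0)
    return prob if prob.ndim else float(prob)


def mh_step(
    v_prev,
    c_prop: float,
    belief_sd: float,
    proposal_sd: float,
    rng: np.random.Generator,
    delta=None,
):
    """One Metropolis–Hastings adjustment; vectorized over ``v_prev``.

    A proposal ``v_prev + delta`` with ``delta ~ N(0, proposal_sd)`` is always
    accepted when it is at least as probable under the truncated target as the
    current value, accepted with probability equal to the density ratio when it
    is less probable, and rejected otherwise.  The proposal increment itself is
    not truncated; out-of-range proposals are rejected through their zero
    target density.  Pass ``delta`` to force a specific increment (testing).
    """
    v_prev = np.asarray(v_prev, dtype=float)
    scalar = v_prev.ndim == 0
    v_prev = np.atleast_1d(v_prev)
    if delta is None:
        delta = rng.normal(0.0, proposal_sd, size=v_prev.shape)
    else:
        delta = np.broadcast_to(np.asarray(delta, dtype=float), v_prev.shape)
    proposal = v_prev + delta
    prob = acceptance_probability(v_prev, proposal, c_prop, belief_sd)
    accept = rng.random(v_prev.shape) < prob
    out = np.where(accept, proposal, v_prev)
    return float(out[0]) if scalar else out


def run_chains(
    config: SimulationConfig,
    rng: np.random.Generator,
    n_iterations: int | None = None,
) -> np.ndarray:
    """Simulate one individual's chains.

    Returns an array of shape ``(n_iterations, n_steps + 1)`` whose entry
    ``(i, t)`` is estimate ``v_t`` of chain ``i``; column 0 holds the prior
    draws.
    """
    n_iter = config.n_iterations if n_iterations is None else n_iterations
    values = np.empty((n_iter, config.n_steps + 1), dtype=float)
    v = sample_prior(config, rng, size=n_iter)
    values[:, 0] = v
    for t in range(1, config.n_steps + 1):
        v = mh_step(v, config.c_prop, config.belief_sd, config.proposal_sd, rng)
        values[:, t] = v
    return values


@dataclass(frozen=True)
class BenefitCurves:
    """Accuracy, cost and net-benefit curves for one simulated individual.

    All four vectors have length ``n_steps + 1``, indexed by adjustment step.
    """

    think_benefit_raw: np.ndarray  # P(v_t > 0.5) over chains
    think_benefit: np.ndarray  # raw rescaled so max = 1
    think_cost: np.ndarray  # linear, 0 -> max_cost
    total_benefit: np.ndarray  # think_benefit - think_cost

    @property
    def n_steps(self) -> int:
        return len(self.think_benefit) - 1


def benefit_curves(chains: np.ndarray, config: SimulationConfig) -> BenefitCurves:
    """Reduce a chain matrix to benefit/cost/total-benefit curves.

    ``think_benefit_raw[t]`` is the fraction of chains with ``v_t > 0.5``
    (strict; equality counts as incorrect).  The raw curve is rescaled by its
    maximum over all steps, including step 0, so the maximum is exactly 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] == 0:
        raise ValueError("chains must be a non-empty 2-D matrix")
    raw = np.mean(chains > 0.5, axis=0)
    peak = raw.max()
    if peak == 0.0:
        raise DegenerateCurveError(
            "accuracy curve is identically zero; cannot rescale to max 1"
        )
    rescaled = raw / peak
    n_steps = chains.shape[1] - 1
    cost = config.max_cost * np.arange(n_steps + 1) / n_steps
    return BenefitCurves(
        think_benefit_raw=raw,
        think_benefit=rescaled,
        think_cost=cost,
        total_benefit=rescaled - cost,
    )


def peak_time(curve: BenefitCurves) -> int:
    """Step at which the total benefit peaks.

    The search runs over ``t in {1, ..., n_steps}`` — a peak after zero
    adjustments is not a thinking-time recommendation — and ties resolve to
    the earliest step.
    """
    return int(np.argmax(curve.total_benefit[1:])) + 1


@dataclass(frozen=True)
class PeakSummary:
    """Population of per-individual total-benefit peak times for one condition."""

    peak_times: np.ndarray
    config: SimulationConfig

    @property
    def mean(self) -> float:
        return float(np.mean(self.peak_times))

    @property
    def min(self) -> int:
        return int(np.min(self.peak_times))

    @property
    def max(self) -> int:
        return int(np.max(self.peak_times))

    @property
    def condition_label(self) -> str:
        return self.config.condition_label

    def summary(self) -> pd.DataFrame:
        """One-row table of the condition and its peak-time statistics."""
        return pd.DataFrame(
            [
                {
                    "c_prop": self.config.c_prop,
                    "max_cost": self.config.max_cost,
                    "prior": self.config.prior,
                    "n_individuals": len(self.peak_times),
                    "mean_peak": self.mean,
                    "min_peak": self.min,
                    "max_peak": self.max,
                }
            ]
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PeakSummary({self.condition_label}: mean={self.mean:.2f}, "
            f"min={self.min}, max={self.max}, n={len(self.peak_times)})"
        )


def _population_peaks(
    config: SimulationConfig,
    max_costs: Sequence[float],
    keep_curves: bool,
) -> tuple[dict[float, np.ndarray], list[BenefitCurves] | None]:
    """Peak times per cost regime, on identical chains across regimes."""
    peaks = {c: np.empty(config.n_individuals, dtype=int) for c in max_costs}
    curves_out: list[BenefitCurves] | None = [] if keep_curves else None
    for i in range(config.n_individuals):
        rng = config.rng_for_individual(i)
        chains = run_chains(config, rng)
        for cost in max_costs:
            curve = benefit_curves(chains, replace(config, max_cost=cost))
            peaks[cost][i] = peak_time(curve)
            if curves_out is not None and cost == config.max_cost:
                curves_out.append(curve)
    return peaks, curves_out


def simulate_population(
    config: SimulationConfig,
    keep_curves: bool = False,
) -> PeakSummary | tuple[PeakSummary, list[BenefitCurves]]:
    """Run the full population simulation for one condition.

    For each of ``config.n_individuals`` simulated individuals: run the
    chains, reduce to benefit curves, take the total-benefit peak time.
    Deterministic for a fixed ``config.seed``.
    """
    peaks, curves = _population_peaks(config, [config.max_cost], keep_curves)
    summary = PeakSummary(peak_times=peaks[config.max_cost], config=config)
    return (summary, curves) if keep_curves else summary


def compare_cost_regimes(
    config: SimulationConfig,
    max_costs: Sequence[float] = (0.0, 0.5),
) -> dict[float, PeakSummary]:
    """Peak-time populations under several cost ceilings on *identical* chains.

    Because the accuracy curve does not depend on the cost schedule, each
    individual's chains are simulated once and re-scored under every
    ``max_cost``; differences between regimes are therefore paired, which is
    how the earlier-and-narrower resource-rational prediction is tested.
    """
    peaks, _ = _population_peaks(config, list(max_costs), keep_curves=False)
    return {
        cost: PeakSummary(peak_times=p, config=replace(config, max_cost=cost))
        for cost, p in peaks.items()
    }


def condition_sweep(
    base: SimulationConfig,
    c_props: Iterable[float] = (0.55, 0.65),
    max_costs: Iterable[float] = (0.0, 0.5),
) -> pd.DataFrame:
    """Peak-time summary table over a difficulty x cost-regime grid.

    Chains are shared across cost regimes within a difficulty (paired design);
    each difficulty uses the same root seed, so populations are comparable.
    """
    rows = []
    for c_prop in c_props:
        cfg = replace(base, c_prop=c_prop)
        for cost, summ in compare_cost_regimes(cfg, list(max_costs)).items():
            rows.append(summ.summary().iloc[0])
    return pd.DataFrame(rows).reset_index(drop=True)
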