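"""Extended SIR spreading engine for misfolded-protein propagation.

Two protein pools evolve on a weighted connectome: normal (susceptible) and
misfolded (infectious) tau.  Each simulation step applies, in order,

1. **spread** - protein leaves region *i* with probability
   ``(1 - stay_probability)`` (scaled by the regional probability ``P_i`` when
   the spread rate is modulated), is split over incident edges proportionally
   to edge weight, and protein travelling inside edge *(i, j)* arrives at *j*
   with per-step probability ``min(1, velocity * dt / length(i, j))``;
2. **synthesis** - normal protein is produced at ``synthesis_rate0 * dt``
   (times ``P_i`` under synthesis modulation);
3. **clearance** - the *existing* regional pools (as they stood before this
   step's synthesis) are multiplied by ``1 - clearance_rate0 * dt`` (times
   ``P_i`` under clearance modulation); the same clearance rate applies to
   normal and misfolded protein, and newly synthesized protein is first
   exposed to clearance on the following step, so the no-transport fixed
   point is ``synthesis_rate0 / clearance_rate0``;
4. **misfolding** - a fraction ``1 - exp(-m_i * transfer_rate * dt)`` (times
   ``P_i`` in the exponent under misfold modulation) of the normal pool
   converts to misfolded protein through contact with the local misfolded
   density ``m_i``.

The primary engine is deterministic (mean-field densities).  A stochastic
agent-based simulator applying the same rules per agent is provided as an
independent reference implementation for validation; it is not used by the
fitting pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .connectome import Connectome, RegionalFactor, RATES

logger = logging.getLogger(__name__)


class SimulationDivergedError(RuntimeError):
    """Raised when a density becomes negative or non-finite during a run."""

    def __init__(self, step: int, message: str):
        super().__init__(f"step {step}: {message}")
        self.step = step


@dataclass
class SIRGlobalParams:
    """Global hyperparameters, constant across regions.

    stay_probability
        Per-step probability that protein remains in its region (tau
        retention); ``1 - stay_probability`` is the exit probability.
    transfer_rate
        Global misfolding-rate scale in the contact term.
    velocity
        Edge traversal rate in length units per step; with unit edge lengths
        and ``velocity * dt >= 1`` an edge is crossed in a single step.
    dt
        Simulation time increment, scaling every rate.
    n_steps
        Number of simulation steps (default 30,000).
    synthesis_rate0, clearance_rate0
        Baseline production and removal rates of protein per unit time.
    """

    stay_probability: float = 0.5
    transfer_rate: float = 1.0
    velocity: float = 1.0
    dt: float = 1.0
    n_steps: int = 30_000
    synthesis_rate0: float = 0.1
    clearance_rate0: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.stay_probability <= 1.0:
            raise ValueError("stay_probability must lie in [0, 1]")
        if self.transfer_rate < 0:
            raise ValueError("transfer_rate must be >= 0")
        if self.velocity <= 0:
            raise ValueError("velocity must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.synthesis_rate0 < 0:
            raise ValueError("synthesis_rate0 must be >= 0")
        if not 0.0 <= self.clearance_rate0 * self.dt < 1.0:
            raise ValueError("per-step clearance (clearance_rate0 * dt) must lie in [0, 1)")


@dataclass
class RegionalModulation:
    """Per-region probabilities scaling exactly one mechanistic rate."""

    probabilities: np.ndarray
    target_rate: str

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p <= 0.0) or np.any(p >= 1.0):
            raise ValueError("modulation probabilities must lie strictly inside (0, 1)")
        self.probabilities = p
        if self.target_rate not in RATES:
            raise ValueError(f"target_rate must be one of {RATES}")


@dataclass
class SIRTrajectory:
    """Per-step normal and misfolded densities, plus final edge occupancies."""

    normal: np.ndarray            # (n_steps, n_regions)
    misfolded: np.ndarray         # (n_steps, n_regions)
    edge_normal: np.ndarray       # (n_regions, n_regions), final step
    edge_misfolded: np.ndarray    # (n_regions, n_regions), final step
    epicenter: tuple[int, ...]
    total_mass: np.ndarray = field(default=None)       # regions + edges, per step
    misfolded_mass: np.ndarray = field(default=None)   # regions + edges, per step

    @property
    def n_steps(self) -> int:
        return self.normal.shape[0]


def standardize_factor(
    factor: RegionalFactor | np.ndarray,
    target_rate: str | None = None,
    allow_constant: bool = True,
) -> RegionalModulation | np.ndarray:
    """Map a regional factor to per-region rate-modulation probabilities.

    Values are z-scored across regions and passed through the standard-normal
    CDF, giving probabilities in (0, 1) that increase strictly with the input:
    regions with higher factor values get proportionally higher rates.  A
    constant factor maps to 0.5 everywhere (all z-scores zero) when
    ``allow_constant`` is set, and errors otherwise.
    """
    values = factor.values if isinstance(factor, RegionalFactor) else np.asarray(factor, float)
    sd = values.std()
    if sd == 0.0:
        if not allow_constant:
            raise ValueError("constant factor cannot be standardized (handling disabled)")
        probs = np.full(values.shape, 0.5)
    else:
        probs = norm.cdf((values - values.mean()) / sd)
        # cdf is strictly monotone but can saturate in float for |z| >~ 8
        probs = np.clip(probs, 1e-12, 1 - 1e-12)
    if target_rate is None:
        return probs
    return RegionalModulation(probs, target_rate)


def _step_operators(
    connectome: Connectome,
    params: SIRGlobalParams,
    modulation: RegionalModulation | None,
):
    """Precompute the per-step transition quantities."""
    W = connectome.weights
    n = connectome.n_regions
    P = np.ones(n)
    target = None
    if modulation is not None:
        P = np.asarray(modulation.probabilities, float)
        if P.shape != (n,):
            raise ValueError("modulation length must match region count")
        target = modulation.target_rate

    strengths = W.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(strengths[:, None] > 0, W / strengths[:, None], 0.0)

    L = connectome.edge_lengths()
    with np.errstate(divide="ignore"):
        q = np.where(W > 0, params.velocity * params.dt / np.where(L > 0, L, np.inf), 0.0)
    if np.any(q > 1.0):
        warnings.warn("edge arrival probability clipped to 1 for some edges "
                      "(velocity*dt exceeds edge length)", RuntimeWarning, stacklevel=3)
    q = np.clip(q, 0.0, 1.0)

    exit_p = np.full(n, 1.0 - params.stay_probability)
    if target == "spread":
        exit_p = exit_p * P
    if np.any(exit_p > 1.0):
        warnings.warn("per-step exit probability clipped to 1", RuntimeWarning, stacklevel=3)
    exit_p = np.clip(exit_p, 0.0, 1.0)
    # regions without edges retain their protein
    exit_p = np.where(strengths > 0, exit_p, 0.0)

    syn = params.synthesis_rate0 * params.dt * (P if target == "synthesis" else 1.0)
    syn = syn * np.ones(n)

    clr = params.clearance_rate0 * params.dt * (P if target == "clearance" else 1.0)
    clr = clr * np.ones(n)
    if np.any(clr >= 1.0):
        warnings.warn("per-step clearance probability clipped below 1", RuntimeWarning,
                      stacklevel=3)
        clr = np.clip(clr, 0.0, 1.0 - 1e-12)

    mis = params.transfer_rate * params.dt * (P if target == "misfold" else 1.0)
    mis = mis * np.ones(n)

    return T, q, exit_p, syn, clr, mis


def equilibrate_normal(
    connectome: Connectome,
    params: SIRGlobalParams,
    modulation: RegionalModulation | None = None,
    tol: float = 1e-10,
    max_steps: int = 100_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate normal-protein dynamics (no misfolded pool) to steady state.

    Returns ``(n_regions_density, edge_occupancy)``.  With movement disabled
    the fixed point is ``synthesis_rate0 / clearance_rate0`` per region;
    synthesis modulation shifts each region's steady state proportionally.
    """
    if params.clearance_rate0 <= 0:
        raise ValueError("equilibration requires clearance_rate0 > 0")
    T, q, exit_p, syn, clr, _ = _step_operators(connectome, params, modulation)
    n = np.zeros(connectome.n_regions)
    E = np.zeros_like(connectome.weights)
    for step in range(max_steps):
        out = n * exit_p
        arrivals = (E * q).sum(axis=0)
        E = E * (1.0 - q) + out[:, None] * T
        n_new = n - out + arrivals
        n_new = n_new * (1.0 - clr) + syn
        resid = np.max(np.abs(n_new - n) / np.maximum(np.abs(n_new), 1e-300))
        n = n_new
        if resid < tol:
            return n, E
    raise RuntimeError(
        f"normal-protein equilibration did not converge in {max_steps} steps "
        f"(last residual {resid:.3e})"
    )


def simulate(
    connectome: Connectome,
    epicenter: int | str | Sequence[int | str],
    params: SIRGlobalParams,
    modulation: RegionalModulation | None = None,
    seed_amount: float = 1.0,
    baseline: tuple[np.ndarray, np.ndarray] | None = None,
    check_every: int = 200,
) -> SIRTrajectory:
    """Run the deterministic density engine for ``params.n_steps`` steps.

    Normal protein is first equilibrated (unless a precomputed ``baseline``
    of regional densities and edge occupancies is supplied), then a misfolded
    seed of ``seed_amount`` total density is injected, split equally across
    the epicenter regions.  Step 0 of the returned trajectory is the seeded
    initial state.
    """
    epi = _resolve_epicenter(connectome, epicenter)
    T, q, exit_p, syn, clr, mis = _step_operators(connectome, params, modulation)

    if baseline is None:
        if params.clearance_rate0 > 0:
            n, En = equilibrate_normal(connectome, params, modulation)
        else:
            n, En = np.zeros(connectome.n_regions), np.zeros_like(connectome.weights)
    else:
        n, En = baseline
        n = np.array(n, float, copy=True)
        En = np.array(En, float, copy=True)

    m = np.zeros(connectome.n_regions)
    m[list(epi)] = seed_amount / len(epi)
    Em = np.zeros_like(connectome.weights)

    n_hist = np.empty((params.n_steps, connectome.n_regions))
    m_hist = np.empty_like(n_hist)
    mass = np.empty(params.n_steps)
    m_mass = np.empty(params.n_steps)
    n_hist[0], m_hist[0] = n, m
    mass[0] = n.sum() + m.sum() + En.sum() + Em.sum()
    m_mass[0] = m.sum() + Em.sum()

    for step in range(1, params.n_steps):
        out_n = n * exit_p
        out_m = m * exit_p
        arr_n = (En * q).sum(axis=0)
        arr_m = (Em * q).sum(axis=0)
        En = En * (1.0 - q) + out_n[:, None] * T
        Em = Em * (1.0 - q) + out_m[:, None] * T
        n = n - out_n + arr_n
        m = m - out_m + arr_m
        n = n * (1.0 - clr) + syn
        m = m * (1.0 - clr)
        conv = n * (-np.expm1(-m * mis))
        n = n - conv
        m = m + conv
        n_hist[step], m_hist[step] = n, m
        mass[step] = n.sum() + m.sum() + En.sum() + Em.sum()
        m_mass[step] = m.sum() + Em.sum()
        if step % check_every == 0 or step == params.n_steps - 1:
            if not (np.all(np.isfinite(n)) and np.all(np.isfinite(m))):
                raise SimulationDivergedError(step, "non-finite density")
            if np.any(n < 0) or np.any(m < 0):
                raise SimulationDivergedError(step, "negative density")

    return SIRTrajectory(n_hist, m_hist, En, Em, epicenter=epi, total_mass=mass,
                         misfolded_mass=m_mass)


def extract_pattern(
    trajectory: SIRTrajectory, step: int, mode: str = "misfolded_density"
) -> np.ndarray:
    """Regional pattern at one timestep: raw misfolded density, or the
    misfolded fraction ``m / (n + m)`` (0 where both pools are empty)."""
    if step >= trajectory.n_steps:
        raise IndexError(f"step {step} out of range for {trajectory.n_steps}-step trajectory")
    m = trajectory.misfolded[step]
    if mode == "misfolded_density":
        return m.copy()
    if mode == "misfolded_fraction":
        total = trajectory.normal[step] + m
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, m / total, 0.0)
        return frac
    raise ValueError(f"unknown pattern mode {mode!r}")


def pattern_timecourse(trajectory: SIRTrajectory, mode: str = "misfolded_density") -> np.ndarray:
    """All per-step patterns as a (n_steps, n_regions) matrix."""
    if mode == "misfolded_density":
        return trajectory.misfolded
    if mode == "misfolded_fraction":
        total = trajectory.normal + trajectory.misfolded
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, trajectory.misfolded / total, 0.0)
    raise ValueError(f"unknown pattern mode {mode!r}")


def _resolve_epicenter(
    connectome: Connectome, epicenter: int | str | Sequence[int | str]
) -> tuple[int, ...]:
    if isinstance(epicenter, (int, np.integer, str)):
        epicenter = [epicenter]
    idx = []
    for e in epicenter:
        i = connectome.index(e) if isinstance(e, str) else int(e)
        if not 0 <= i < connectome.n_regions:
            raise ValueError(f"epicenter index {i} out of range")
        idx.append(i)
    if not idx:
        raise ValueError("empty epicenter")
    return tuple(idx)


# ---------------------------------------------------------------------------
# Stochastic agent-based reference implementation
# ---------------------------------------------------------------------------

def simulate_agents(
    connectome: Connectome,
    epicenter: int | str | Sequence[int | str],
    params: SIRGlobalParams,
    modulation: RegionalModulation | None = None,
    seed_amount: float = 1.0,
    agents_per_density: int = 10_000,
    rng: np.random.Generator | int | None = None,
    record_steps: Sequence[int] | None = None,
) -> dict[int, np.ndarray]:
    """Monte-Carlo agent simulation applying the same per-step rules per agent.

    Each agent is one quantum of ``1 / agents_per_density`` density.  Returns
    the misfolded density estimate (misfolded agent count divided by
    ``agents_per_density``) per region at the requested steps.  Serves as an
    independent stochastic reference for the density engine.
    """
    rng = np.random.default_rng(rng)
    epi = _resolve_epicenter(connectome, epicenter)
    T, q, exit_p, syn, clr, mis = _step_operators(connectome, params, modulation)
    n_reg = connectome.n_regions
    K = agents_per_density

    if params.clearance_rate0 > 0:
        n0, En0 = equilibrate_normal(connectome, params, modulation)
    else:
        n0 = np.zeros(n_reg)
        En0 = np.zeros_like(connectome.weights)

    # agent state: region index, edge target (-1 if in a region), misfolded flag
    region = np.repeat(np.arange(n_reg), np.round(n0 * K).astype(int))
    target = np.full(region.size, -1, dtype=int)
    # normal protein in transit at equilibrium starts inside the edges
    edge_counts = np.round(En0 * K).astype(int)
    src, dst = np.nonzero(edge_counts)
    region = np.concatenate([region, np.repeat(src, edge_counts[src, dst])])
    target = np.concatenate([target, np.repeat(dst, edge_counts[src, dst])])
    state = np.zeros(region.size, dtype=bool)

    seed_counts = np.zeros(n_reg, dtype=int)
    for i in epi:
        seed_counts[i] = int(round(seed_amount / len(epi) * K))
    region = np.concatenate([region, np.repeat(np.arange(n_reg), seed_counts)])
    target = np.concatenate([target, np.full(seed_counts.sum(), -1, dtype=int)])
    state = np.concatenate([state, np.ones(seed_counts.sum(), dtype=bool)])

    record = sorted(set(record_steps or [params.n_steps - 1]))
    out: dict[int, np.ndarray] = {}
    if 0 in record:
        out[0] = np.bincount(region[state], minlength=n_reg) / K

    cum_T = np.cumsum(T, axis=1)
    for step in range(1, max(record) + 1):
        in_region = target < 0
        was_in_edge = ~in_region  # arrivals use the pre-step edge state
        # spread: region agents exit onto an edge
        exiting = in_region & (rng.random(region.size) < exit_p[region])
        if exiting.any():
            u = rng.random(exiting.sum())
            rows = cum_T[region[exiting]]
            target[exiting] = (u[:, None] < rows).argmax(axis=1)
        # spread: edge agents arrive
        arriving = was_in_edge & (rng.random(region.size) < q[region, np.maximum(target, 0)])
        region[arriving] = target[arriving]
        target[arriving] = -1
        # clearance of existing agents inside regions, then synthesis births
        # (newly made protein is first exposed to clearance next step)
        in_region = target < 0
        cleared = in_region & (rng.random(region.size) < clr[region])
        keep = ~cleared
        region, target, state = region[keep], target[keep], state[keep]
        born = rng.poisson(syn * K)
        if born.sum():
            region = np.concatenate([region, np.repeat(np.arange(n_reg), born)])
            target = np.concatenate([target, np.full(born.sum(), -1, dtype=int)])
            state = np.concatenate([state, np.zeros(born.sum(), dtype=bool)])
        # misfolding: conversion probability from local misfolded density
        in_region = target < 0
        m_density = np.bincount(region[state & in_region], minlength=n_reg) / K
        p_conv = -np.expm1(-m_density * mis)
        convert = in_region & ~state & (rng.random(region.size) < p_conv[region])
        state[convert] = True
        if step in record:
            out[step] = np.bincount(region[state & (target < 0)], minlength=n_reg) / K
    return out
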