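"""Connectome preprocessing, model-space enumeration and surrogate nulls.

The model space crosses connectomes with regional factors and the four
mechanistic rates: ``n_connectomes`` connectome-only models plus
``n_connectomes * n_factors * 4`` factor models.  After fitting, the
best-performing rate is retained per (connectome, factor) pair, and each
retained model is gated against a null distribution of fits obtained on
surrogate connectomes that preserve the degree sequence exactly and the
strength sequence approximately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .connectome import Connectome, RegionalFactor, RATES
from .fitting import ModelFitResult, fit_model
from .sir import SIRGlobalParams

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Connectome preprocessing
# ---------------------------------------------------------------------------

def preprocess_connectome(
    raw: np.ndarray,
    labels: Sequence[str] | None = None,
    kind: str = "similarity",
    fc_threshold: float = 0.40,
    centroids: np.ndarray | None = None,
    name: str = "connectome",
) -> Connectome:
    """Normalize a raw similarity/connectivity matrix into a Connectome.

    The arctanh (Fisher) transform is applied elementwise after clipping
    inputs into (-1, 1); negative values are zeroed, the diagonal is zeroed
    and the matrix symmetrized by averaging.  For functional-type inputs
    (``kind="fc"``) a proportional threshold retains the top ``fc_threshold``
    fraction of positive connections (supported fractions 0.10-0.40).
    A fully disconnected result is flagged with a warning rather than an
    error.
    """
    A = np.asarray(raw, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("input matrix must be square")
    if not np.all(np.isfinite(A)):
        raise ValueError("input matrix must be finite")
    if kind not in ("similarity", "fc", "sc"):
        raise ValueError(f"unknown connectome kind {kind!r}")

    W = np.arctanh(np.clip(A, -1.0 + 1e-12, 1.0 - 1e-12))
    W[W < 0] = 0.0
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2.0

    if kind == "fc":
        if not 0.0 < fc_threshold <= 1.0:
            raise ValueError("fc_threshold must lie in (0, 1]")
        W = proportional_threshold(W, fc_threshold)

    labels = list(labels) if labels is not None else [f"r{i:03d}" for i in range(A.shape[0])]
    conn = Connectome(W, labels, centroids, name=name)
    if not conn.is_connected():
        logger.warning("preprocessed connectome %r contains isolated regions "
                       "or disconnected components", name)
    return conn


def proportional_threshold(W: np.ndarray, fraction: float) -> np.ndarray:
    """Keep the top ``fraction`` of positive off-diagonal connections
    (floor of fraction x positive edge count), zeroing the rest."""
    iu = np.triu_indices_from(W, k=1)
    vals = W[iu]
    positive = vals > 0
    n_keep = math.floor(fraction * positive.sum())
    out = np.zeros_like(W)
    if n_keep > 0:
        order = np.argsort(vals)[::-1][:n_keep]
        keep_rows, keep_cols = iu[0][order], iu[1][order]
        out[keep_rows, keep_cols] = vals[order]
        out = out + out.T
    return out


# ---------------------------------------------------------------------------
# Model-space enumeration and reduction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelPlan:
    """One model to fit: a connectome, optionally with a (factor, rate) pair."""

    connectome: str
    factor: str | None = None
    rate: str | None = None


def enumerate_model_space(
    connectome_names: Sequence[str],
    factor_names: Sequence[str],
    rates: Sequence[str] = RATES,
) -> list[ModelPlan]:
    """All connectome-only models plus every (connectome, factor, rate) triple."""
    if not connectome_names:
        raise ValueError("at least one connectome is required")
    plans = [ModelPlan(c) for c in connectome_names]
    plans += [
        ModelPlan(c, f, r)
        for c in connectome_names
        for f in factor_names
        for r in rates
    ]
    return plans


def select_best_rate(results: Sequence[ModelFitResult]) -> list[ModelFitResult]:
    """Reduce to one model per (connectome, factor): the best-performing rate.

    Connectome-only rows are always kept.  Ties between rates are broken by
    the fixed rate order (synthesis, clearance, spread, misfold).  A
    (connectome, factor) pair missing any of the four rate variants is an
    error naming the gap.
    """
    baselines = [r for r in results if r.factor_name is None]
    grouped: dict[tuple[str, str], dict[str, ModelFitResult]] = {}
    for res in results:
        if res.factor_name is None:
            continue
        grouped.setdefault((res.connectome_name, res.factor_name), {})[res.rate_name] = res
    reduced = list(baselines)
    for (conn, fac), by_rate in grouped.items():
        missing = [r for r in RATES if r not in by_rate]
        if missing:
            raise ValueError(
                f"model ({conn!r}, {fac!r}) is missing rate variant(s): {missing}"
            )
        best_rate = max(RATES, key=lambda r: (by_rate[r].r_best, -RATES.index(r)))
        reduced.append(by_rate[best_rate])
    return reduced


def fold_change_improvement(r_with_factor: float, r_connectome_only: float) -> float:
    """Relative gain of a factor model over its connectome-only baseline:
    ``(r_with - r_only) / r_only``.  Undefined (NaN) for non-positive
    baselines; negative outputs are legal (the factor hurt the fit)."""
    if r_connectome_only <= 0:
        return float("nan")
    return (r_with_factor - r_connectome_only) / r_connectome_only


# ---------------------------------------------------------------------------
# Surrogate connectomes and null distributions
# ---------------------------------------------------------------------------

def scramble_connectome(
    connectome: Connectome,
    seed: int | np.random.Generator,
    swaps_per_edge: int = 10,
    strength_iterations: int = 50,
) -> Connectome:
    """Degree- and strength-preserving surrogate network.

    The binary topology is rewired by double-edge swaps (preserving the degree
    sequence exactly); the original weight multiset is then reassigned to the
    rewired edges by rank matching against the endpoint-strength sum, and the
    weights are refined by iterative proportional adjustment so nodal
    strengths closely approximate the originals.  Total edge weight is
    restored exactly.  Rewiring-invariant graphs (e.g. complete graphs with
    equal weights) come back unchanged.
    """
    rng = np.random.default_rng(seed)
    W = connectome.weights
    edges = np.transpose(np.nonzero(np.triu(W, 1)))
    if len(edges) < 2:
        raise ValueError("need >= 2 edges to scramble a connectome")
    edge_set = {tuple(e) for e in map(tuple, edges)}
    edges = [tuple(e) for e in edges]

    target_swaps = swaps_per_edge * len(edges)
    done = 0
    tries = 0
    max_tries = 100 * target_swaps
    while done < target_swaps and tries < max_tries:
        tries += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        (a, b), (c, d) = edges[i], edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, d) and (c, b)
        if len({a, b, c, d}) < 4:
            continue
        e1 = (min(a, d), max(a, d))
        e2 = (min(c, b), max(c, b))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edges[i], edges[j] = e1, e2
        edge_set.update((e1, e2))
        done += 1

    strengths = connectome.strengths()
    new_edges = np.array(edges)
    scores = strengths[new_edges[:, 0]] + strengths[new_edges[:, 1]]
    weights_sorted = np.sort(W[np.triu_indices_from(W, 1)])
    weights_sorted = weights_sorted[weights_sorted > 0]
    order = np.argsort(scores, kind="stable")
    out = np.zeros_like(W)
    for rank, edge_idx in enumerate(order):
        a, b = new_edges[edge_idx]
        out[a, b] = out[b, a] = weights_sorted[rank]
    # iterative proportional adjustment: scale each edge by the geometric mean
    # of its endpoints' strength-correction ratios, then restore total weight
    mask = out > 0
    for _ in range(strength_iterations):
        cur = out.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(cur > 0, strengths / cur, 1.0)
        out = np.where(mask, out * np.sqrt(ratio[:, None] * ratio[None, :]), 0.0)
    total = W.sum()
    if out.sum() > 0:
        out *= total / out.sum()
    return Connectome(out, list(connectome.labels),
                      None if connectome.centroids is None else connectome.centroids.copy(),
                      name=f"{connectome.name}_surrogate")


@dataclass
class NullDistribution:
    """Null fit distribution from surrogate connectomes, with the 95% gate."""

    r_values: np.ndarray
    mean: float
    ci95: tuple[float, float]
    observed_r: float
    significant: bool


def null_distribution(
    connectome: Connectome,
    empirical: np.ndarray,
    observed_r: float,
    n_surrogates: int = 1000,
    seed: int | np.random.Generator = 0,
    factor: RegionalFactor | None = None,
    rate: str | None = None,
    grid: Mapping[str, Sequence[float]] | Sequence[tuple] | None = None,
    epicenter=0,
    base_params: SIRGlobalParams | None = None,
    mode: str = "misfolded_density",
) -> NullDistribution:
    """Refit the model on rewired surrogate connectomes.

    By default the observed-data hyperparameter grid (or single triple) is
    reused per surrogate; pass a full grid to re-tune each null fit.  The
    model is significant when the observed correlation exceeds the upper
    bound of the null 95% interval (one-sided: higher r is better).
    """
    if n_surrogates < 2:
        raise ValueError("n_surrogates must be >= 2")
    rng = np.random.default_rng(seed)
    r_values = np.empty(n_surrogates)
    for k in range(n_surrogates):
        surrogate = scramble_connectome(connectome, rng)
        res = fit_model(surrogate, empirical, factor=factor, rate=rate,
                        grid=grid, epicenter=epicenter,
                        base_params=base_params, mode=mode)
        r_values[k] = res.r_best
    lo, hi = np.percentile(r_values, [2.5, 97.5])
    return NullDistribution(
        r_values=r_values,
        mean=float(r_values.mean()),
        ci95=(float(lo), float(hi)),
        observed_r=float(observed_r),
        significant=bool(observed_r > hi),
    )


def run_model_space(
    connectomes: Mapping[str, Connectome],
    factors: Mapping[str, RegionalFactor],
    empirical: np.ndarray,
    grid: Mapping[str, Sequence[float]] | Sequence[tuple] | None = None,
    epicenter=0,
    base_params: SIRGlobalParams | None = None,
    mode: str = "misfolded_density",
) -> list[ModelFitResult]:
    """Fit every model in the enumerated space and return all results."""
    plans = enumerate_model_space(list(connectomes), list(factors))
    results = []
    for plan in plans:
        results.append(fit_model(
            connectomes[plan.connectome], empirical,
            factor=factors[plan.factor] if plan.factor else None,
            rate=plan.rate, grid=grid, epicenter=epicenter,
            base_params=base_params, mode=mode,
        ))
    return results
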