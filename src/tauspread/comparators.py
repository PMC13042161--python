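"""Alternative spreading models and connectome-similarity metrics.

These comparators test whether conclusions from the SIR engine are specific
to its mechanistic assumptions: a conservative linear-diffusion model (signal
random-walks along the connectome from the epicenter), and an inferential
statistic relating a tau spreading sequence to connectivity-derived distances
from the epicenter.  A plug-in spreading function can replace the diffusion
comparator with any other epicenter-seeded model.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.sparse.csgraph import dijkstra
from scipy.stats import pearsonr, zscore
from skimage.metrics import structural_similarity

from .connectome import Connectome
from .sir import _resolve_epicenter

logger = logging.getLogger(__name__)


def diffusion_comparator(
    connectome: Connectome,
    epicenter,
    n_steps: int = 1000,
    step_size: float = 0.5,
) -> np.ndarray:
    """Linear diffusion of a unit seed along the connectome.

    Per step a fraction ``step_size`` of each region's signal leaves along
    incident edges in proportion to edge weight (a lazy random walk):
    ``x(t+1) = (1 - tau) x(t) + tau W_rn^T x(t)`` with row-normalized weights,
    conserving total signal.  Returns the (n_steps, n_regions) pattern
    time course; on a connected graph the long-time pattern is proportional
    to nodal strength (the walk's stationary distribution).
    """
    if not 0.0 < step_size <= 1.0:
        raise ValueError("step_size must lie in (0, 1]")
    epi = _resolve_epicenter(connectome, epicenter)
    W = connectome.weights
    s = W.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(s[:, None] > 0, W / s[:, None], 0.0)
    # isolated regions keep their signal
    leave = np.where(s > 0, step_size, 0.0)
    x = np.zeros(connectome.n_regions)
    x[list(epi)] = 1.0 / len(epi)
    out = np.empty((n_steps, connectome.n_regions))
    out[0] = x
    for t in range(1, n_steps):
        x = x - leave * x + (leave * x) @ T
        out[t] = x
    return out


def connectivity_distance(
    connectome: Connectome, epicenter, method: str = "shortest_path"
) -> np.ndarray:
    """Connectivity-derived distance of every region from the epicenter.

    ``shortest_path``: Dijkstra over inverse-weight edge costs (strong
    connections are short); ``inverse``: direct 1/weight to the epicenter
    (infinite for unconnected pairs).  Multi-region epicenters take the
    minimum distance over seeds.
    """
    epi = _resolve_epicenter(connectome, epicenter)
    W = connectome.weights
    if method == "shortest_path":
        with np.errstate(divide="ignore"):
            cost = np.where(W > 0, 1.0 / W, 0.0)
        dist = dijkstra(cost, directed=False, indices=list(epi))
    elif method == "inverse":
        with np.errstate(divide="ignore"):
            dist = np.where(W[list(epi)] > 0, 1.0 / W[list(epi)], np.inf)
    else:
        raise ValueError(f"unknown distance method {method!r}")
    d = dist.min(axis=0)
    d[list(epi)] = 0.0
    return d


def connectivity_distance_statistic(
    connectome: Connectome,
    epicenter,
    tau_sequence: np.ndarray,
    method: str = "shortest_path",
) -> float:
    """Pearson correlation between connectivity-derived epicenter distance
    and a regional tau spreading sequence.

    Regions unreachable from the epicenter (infinite distance) are excluded,
    with the excluded count logged.
    """
    tau_sequence = np.asarray(tau_sequence, float)
    d = connectivity_distance(connectome, epicenter, method)
    finite = np.isfinite(d)
    n_excluded = int((~finite).sum())
    if n_excluded:
        logger.info("excluding %d region(s) disconnected from the epicenter", n_excluded)
    if tau_sequence[finite].std() == 0:
        raise ValueError("tau sequence has zero variance over reachable regions")
    return float(pearsonr(d[finite], tau_sequence[finite]).statistic)


def connectome_similarity(
    A: Connectome | np.ndarray,
    B: Connectome | np.ndarray,
    ssim_window: int = 7,
) -> tuple[float, float, float]:
    """(SSIM, cosine, Pearson) similarity between two connectomes.

    Cosine and Pearson are computed on the vectorized upper-triangle entries;
    SSIM treats the full matrices as images after joint min-max scaling, with
    a fixed window (shrunk to an odd size fitting small matrices).
    """
    WA = A.weights if isinstance(A, Connectome) else np.asarray(A, float)
    WB = B.weights if isinstance(B, Connectome) else np.asarray(B, float)
    if WA.shape != WB.shape:
        raise ValueError("connectomes must have the same shape and region ordering")
    iu = np.triu_indices_from(WA, k=1)
    a, b = WA[iu], WB[iu]
    cosine = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
    pearson = float(pearsonr(a, b).statistic)
    lo = min(WA.min(), WB.min())
    hi = max(WA.max(), WB.max())
    span = hi - lo if hi > lo else 1.0
    win = min(ssim_window, WA.shape[0] - (1 - WA.shape[0] % 2))
    ssim = float(structural_similarity(
        (WA - lo) / span, (WB - lo) / span, win_size=win, data_range=1.0
    ))
    return ssim, cosine, pearson


def strength_difference(A: Connectome, B: Connectome) -> np.ndarray:
    """Per-region difference of z-scored nodal strengths, A minus B."""
    if A.n_regions != B.n_regions:
        raise ValueError("connectomes must have the same region count")
    return zscore(A.strengths()) - zscore(B.strengths())
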