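"""Synthetic connectomes, regional factors, receptor panels and cohorts.

Every downstream stage of the pipeline is testable without any external data:
the generators here produce weighted connectomes of several topologies,
spatially-smooth regional factor maps, strictly-positive receptor panels, and
cohort tau tables whose positive participants carry signal generated by an
actual SIR simulation from a known epicenter (with known factor/rate
modulation), so that ground truth for every recovery experiment — epicenter,
factor, rate, per-participant pseudotimes — is known exactly and stored in a
sidecar that analysis code never reads.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from .connectome import Connectome, RegionalFactor, RATES
from .quantify import CohortTauTable
from .receptors import PANEL_MARKERS, ReceptorPanel
from .sir import SIRGlobalParams, simulate, standardize_factor

CONNECTOME_KINDS = ("geometric", "modular", "fc_like", "dense")

#: Desk-scale spreading parameters used when generating cohorts.  High tau
#: retention and slow edge traversal relative to the step size let the
#: epidemic unfold over hundreds of steps, so the cohort spans clearly
#: distinguishable disease stages; 2,000 steps at dt=1 reaches the plateau on
#: a 40-region network while keeping recovery experiments fast.
DEFAULT_COHORT_SIR = SIRGlobalParams(
    stay_probability=0.9, transfer_rate=1.0, velocity=0.05,
    dt=1.0, n_steps=2000, synthesis_rate0=0.1, clearance_rate0=0.1,
)


class InvalidSpecError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Ground-truth configuration of a synthetic study.

    ``true_factor_name``/``true_rate`` select which mechanistic rate (if any)
    the generating factor modulates; ``noise_sd`` is the per-region Gaussian
    measurement noise in SUVR-like units.
    """

    n_regions: int = 40
    n_participants_positive: int = 600
    n_participants_reference: int = 200
    epicenter_index: int = 0
    true_factor_name: str | None = None
    true_rate: str | None = None
    noise_sd: float = 0.1
    seed: int = 0
    connectome_kind: str = "geometric"

    def __post_init__(self) -> None:
        if self.n_regions < 3:
            raise InvalidSpecError("n_regions must be >= 3")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if not 0 <= self.epicenter_index < self.n_regions:
            raise InvalidSpecError("epicenter_index must be < n_regions")
        if self.connectome_kind not in CONNECTOME_KINDS:
            raise InvalidSpecError(f"connectome_kind must be one of {CONNECTOME_KINDS}")
        if self.true_rate is not None and self.true_rate not in RATES:
            raise InvalidSpecError(f"true_rate must be one of {RATES}")


def _labels(n: int) -> list[str]:
    return [f"r{i:03d}" for i in range(n)]


def generate_connectome(
    spec: SyntheticSpec,
    density: float = 0.3,
    fc_threshold: float = 0.40,
) -> Connectome:
    """Generate a synthetic connectome of the requested kind.

    geometric
        Regions placed uniformly in the unit cube; weight exp(-d / 0.3) times
        a symmetric log-normal jitter (anatomical connectomes carry
        heavy-tailed, log-normally distributed weights, which is what makes
        regional connection profiles distinctive), thresholded to the target
        edge density while keeping the minimum spanning tree (so the graph
        stays connected); centroids attached.
    modular
        Dense weighted graph with two modules (stronger within-module
        weights).
    fc_like
        Correlation matrix from a latent two-factor model, arctanh
        normalized, positive, proportionally thresholded.
    dense
        Fully connected with uniform random weights.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_regions
    kind = spec.connectome_kind

    if kind == "geometric":
        pts = rng.uniform(size=(n, 3))
        D = squareform(pdist(pts))
        jitter = rng.lognormal(mean=0.0, sigma=1.0, size=(n, n))
        jitter = np.sqrt(jitter * jitter.T)
        W = np.exp(-D / 0.3) * jitter
        np.fill_diagonal(W, 0.0)
        n_keep = max(int(round(density * n * (n - 1) / 2)), n - 1)
        iu = np.triu_indices(n, 1)
        order = np.argsort(W[iu])[::-1]
        keep = np.zeros_like(W, dtype=bool)
        keep[iu[0][order[:n_keep]], iu[1][order[:n_keep]]] = True
        # union with MST over distances so the graph is always connected
        mst = minimum_spanning_tree(D).toarray() > 0
        keep |= mst | mst.T
        keep |= keep.T
        W = np.where(keep, W, 0.0)
        return Connectome(W, _labels(n), centroids=pts, name="geometric")

    if kind == "modular":
        module = (np.arange(n) >= n // 2).astype(int)
        base = np.where(module[:, None] == module[None, :], 1.0, 0.25)
        noise = rng.lognormal(mean=0.0, sigma=0.4, size=(n, n))
        W = base * (noise + noise.T) / 2
        np.fill_diagonal(W, 0.0)
        return Connectome(W, _labels(n), name="modular")

    if kind == "fc_like":
        from .search import preprocess_connectome  # avoids import cycle at module load

        loadings = rng.normal(size=(n, 2))
        ts = loadings @ rng.normal(size=(2, 200)) + rng.normal(size=(n, 200))
        C = np.corrcoef(ts)
        return preprocess_connectome(C, _labels(n), kind="fc",
                                     fc_threshold=fc_threshold, name="fc_like")

    # dense
    U = rng.uniform(0.1, 1.0, size=(n, n))
    W = (U + U.T) / 2
    np.fill_diagonal(W, 0.0)
    return Connectome(W, _labels(n), name="dense")


def generate_regional_factor(
    connectome: Connectome,
    smoothness: float = 0.5,
    seed: int = 0,
    name: str = "factor",
    zero_variance: bool = False,
    n_smooth: int = 8,
) -> RegionalFactor:
    """Regional factor with tunable spatial autocorrelation.

    A standard-normal draw is mixed with its graph-smoothed version (repeated
    neighbor averaging over the connectome): smoothness 0 gives i.i.d. values,
    smoothness 1 gives strongly autocorrelated neighbor values.  The
    ``zero_variance`` option forces a constant map (useful for degenerate-
    standardization tests).
    """
    if not 0.0 <= smoothness <= 1.0:
        raise ValueError("smoothness must lie in [0, 1]")
    n = connectome.n_regions
    if zero_variance:
        return RegionalFactor(name, np.ones(n))
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n)
    W = connectome.weights
    s = W.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(s[:, None] > 0, W / s[:, None], 0.0)
    smooth = eps.copy()
    for _ in range(n_smooth):
        smooth = T @ smooth
    if smooth.std() > 0:
        smooth = (smooth - smooth.mean()) / smooth.std()
    values = (1.0 - smoothness) * eps + smoothness * smooth
    return RegionalFactor(name, values)


@dataclass
class GroundTruth:
    """Generator-side truth for recovery experiments; analysis code must
    never read it."""

    epicenter_index: int
    factor_name: str | None
    rate: str | None
    pseudotimes: np.ndarray          # per positive participant, in steps
    signal: np.ndarray               # positives x regions added signal (gain * m-hat)
    baseline_means: np.ndarray       # per region
    noise_sd: float
    gain: float
    plateau: np.ndarray              # per region max of normalized misfolded density
    factor_values: np.ndarray | None = None

    def latent_labels(self, threshold_frac: float = 0.1) -> np.ndarray:
        """Positive-group latent tau-positivity per participant x region:
        misfolded density at the participant's pseudotime exceeds
        ``threshold_frac`` of the region's trajectory plateau."""
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(self.plateau > 0, self.signal / (self.gain * self.plateau), 0.0)
        return rel > threshold_frac

    def bayes_classify(self, table: CohortTauTable, threshold_frac: float = 0.1
                       ) -> tuple[np.ndarray, np.ndarray]:
        """Bayes-optimal positivity calls from the true generative mixture.

        For each region the negative class is Gaussian around the baseline
        mean (reference participants plus unreached positives), and the
        positive class is an equal-weight mixture of Gaussians shifted by the
        reached participants' true added signals.  Returns (calls, labels)
        over all participants x regions, where reference rows are labelled
        negative.
        """
        pos_mask = table.group_mask("positive")
        labels = np.zeros(table.values.shape, dtype=bool)
        labels[pos_mask] = self.latent_labels(threshold_frac)
        calls = np.zeros_like(labels)
        sd = max(self.noise_sd, 1e-9)
        for j in range(table.n_regions):
            x = table.values[:, j]
            lab = labels[:, j]
            mu0 = self.baseline_means[j]
            shifts = self.signal[self.latent_labels(threshold_frac)[:, j], j]
            n1 = lab.sum()
            if n1 == 0 or shifts.size == 0:
                continue
            pi1 = n1 / lab.size
            log_p0 = np.log1p(-pi1) + norm.logpdf(x, mu0, sd)
            comp = norm.logpdf(x[:, None], mu0 + shifts[None, :], sd)
            log_p1 = np.log(pi1 / shifts.size) + \
                np.logaddexp.reduce(comp, axis=1)
            calls[:, j] = log_p1 > log_p0
        return calls, labels


def generate_cohort(
    spec: SyntheticSpec,
    connectome: Connectome,
    factor: RegionalFactor | None = None,
    sir_params: SIRGlobalParams | None = None,
    gain: float = 1.0,
    burn_in_mass_frac: float = 0.05,
    late_stage_margin: float = 0.3,
) -> tuple[CohortTauTable, GroundTruth]:
    """Generate a cohort whose positive participants carry SIR-derived signal.

    Reference participants are drawn from a region-specific Gaussian baseline
    (mean drawn once per region, SD = ``noise_sd``).  Each positive
    participant gets a latent pseudotime drawn uniformly over the burn-in-free
    portion of the trajectory — from the step where total misfolded mass
    exceeds ``burn_in_mass_frac`` of its maximum to shortly
    (``late_stage_margin`` of the spreading span) after the last region's
    half-plateau rise; their regional values are baseline + ``gain`` x
    normalized misfolded density at that pseudotime + noise.  Regions
    downstream of the epicenter thus show bimodal pooled distributions across
    the cohort.
    """
    if spec.true_rate is not None and factor is None:
        raise ValueError("a factor must be provided when true_rate is set")
    if connectome.n_regions != spec.n_regions:
        raise ValueError("connectome size must match spec.n_regions")
    params = sir_params or DEFAULT_COHORT_SIR
    modulation = (
        standardize_factor(factor, spec.true_rate) if spec.true_rate else None
    )
    traj = simulate(connectome, spec.epicenter_index, params, modulation)
    m = traj.misfolded
    m_max = m.max()
    m_hat = m / m_max if m_max > 0 else m

    rng = np.random.default_rng(spec.seed)
    baseline_means = rng.uniform(1.0, 1.4, size=spec.n_regions)

    # sample pseudotimes from the end of burn-in to shortly after the last
    # region's rise: the cohort then spans clearly graded disease stages
    # (epicenter identifiable from the group map) while every region is
    # reached by a non-negligible subpopulation (mixtures identifiable)
    total = m_hat.sum(axis=1)
    start = int(np.argmax(total >= burn_in_mass_frac * total.max()))
    plateau = m_hat.max(axis=0)
    rises = [
        int(np.argmax(m_hat[:, j] >= 0.5 * plateau[j]))
        for j in range(spec.n_regions) if plateau[j] > 0
    ]
    t_last = max(rises) if rises else start
    stop = min(params.n_steps, int(t_last + late_stage_margin * (t_last - start)) + 1)
    eligible = np.arange(start, max(stop, start + 1))
    pseudotimes = rng.choice(eligible, size=spec.n_participants_positive, replace=True)

    signal = gain * m_hat[pseudotimes]
    n_ref = spec.n_participants_reference
    n_pos = spec.n_participants_positive
    ref_values = baseline_means + rng.normal(0, spec.noise_sd, size=(n_ref, spec.n_regions))
    pos_values = baseline_means + signal + \
        rng.normal(0, spec.noise_sd, size=(n_pos, spec.n_regions))
    values = np.vstack([ref_values, pos_values])
    values = np.maximum(values, 1e-3)  # tracer values are strictly positive

    table = CohortTauTable(
        values,
        [f"ref{i:03d}" for i in range(n_ref)] + [f"pos{i:03d}" for i in range(n_pos)],
        ["reference"] * n_ref + ["positive"] * n_pos,
        list(connectome.labels),
    )
    truth = GroundTruth(
        epicenter_index=spec.epicenter_index,
        factor_name=spec.true_factor_name if factor is not None else None,
        rate=spec.true_rate,
        pseudotimes=pseudotimes,
        signal=signal,
        baseline_means=baseline_means,
        noise_sd=spec.noise_sd,
        gain=gain,
        plateau=m_hat.max(axis=0),
        factor_values=None if factor is None else factor.values.copy(),
    )
    return table, truth


def generate_receptor_panel(
    n_regions: int, seed: int = 0, constant: float | None = None
) -> ReceptorPanel:
    """Strictly positive 19-marker panel; ``constant`` forces every map to a
    single value (debug option for the closed-form ratio checks)."""
    if constant is not None:
        return ReceptorPanel({m: np.full(n_regions, float(constant)) for m in PANEL_MARKERS})
    rng = np.random.default_rng(seed)
    return ReceptorPanel({
        m: rng.lognormal(mean=0.0, sigma=0.5, size=n_regions) for m in PANEL_MARKERS
    })


# ---------------------------------------------------------------------------
# Sidecar I/O
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize ground truth to a YAML sidecar next to the cohort table."""
    data = asdict(truth)
    for key, val in data.items():
        if isinstance(val, np.ndarray):
            data[key] = val.tolist()
    Path(path).write_text(yaml.safe_dump(data))


def read_ground_truth(path: str | Path) -> GroundTruth:
    data = yaml.safe_load(Path(path).read_text())
    for key in ("pseudotimes", "signal", "baseline_means", "plateau", "factor_values"):
        if data.get(key) is not None:
            data[key] = np.asarray(data[key])
    return GroundTruth(**data)
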