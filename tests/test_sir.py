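import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

import tauspread as ts
from tauspread.sir import SIRGlobalParams, _resolve_epicenter


def naive_sir(W, lengths, epicenter, params, P=None, target=None, n_steps=5, seed_amount=1.0,
              n0=None, En0=None):
    """Independent loop-and-dict reimplementation of the per-step rules."""
    n_reg = W.shape[0]
    P = np.ones(n_reg) if P is None else P
    n = np.zeros(n_reg) if n0 is None else np.array(n0, float)
    m = np.zeros(n_reg)
    m[epicenter] = seed_amount
    En = {}
    Em = {}
    edges = [(i, j) for i in range(n_reg) for j in range(n_reg) if W[i, j] > 0]
    for e in edges:
        En[e] = 0.0 if En0 is None else float(En0[e])
        Em[e] = 0.0
    hist_n, hist_m = [n.copy()], [m.copy()]
    for _ in range(n_steps - 1):
        out_n = np.zeros(n_reg)
        out_m = np.zeros(n_reg)
        arr_n = np.zeros(n_reg)
        arr_m = np.zeros(n_reg)
        for i in range(n_reg):
            s = W[i].sum()
            if s == 0:
                continue
            exit_p = (1 - params.stay_probability) * (P[i] if target == "spread" else 1.0)
            exit_p = min(max(exit_p, 0.0), 1.0)
            out_n[i] = n[i] * exit_p
            out_m[i] = m[i] * exit_p
        new_En, new_Em = {}, {}
        for (i, j) in edges:
            q = min(1.0, params.velocity * params.dt / lengths[i, j])
            arr_n[j] += En[(i, j)] * q
            arr_m[j] += Em[(i, j)] * q
            share = W[i, j] / W[i].sum()
            new_En[(i, j)] = En[(i, j)] * (1 - q) + out_n[i] * share
            new_Em[(i, j)] = Em[(i, j)] * (1 - q) + out_m[i] * share
        En, Em = new_En, new_Em
        n = n - out_n + arr_n
        m = m - out_m + arr_m
        clr = params.clearance_rate0 * params.dt * np.where(target == "clearance", P, 1.0)
        n = n * (1 - clr) + params.synthesis_rate0 * params.dt * np.where(target == "synthesis", P, 1.0)
        m = m * (1 - clr)
        mis = params.transfer_rate * params.dt * np.where(target == "misfold", P, 1.0)
        conv = n * (1 - np.exp(-m * mis))
        n = n - conv
        m = m + conv
        hist_n.append(n.copy())
        hist_m.append(m.copy())
    return np.array(hist_n), np.array(hist_m)


class TestStandardizeFactor:
    def test_constant_factor_maps_to_half(self):
        probs = ts.standardize_factor(np.full(5, 3.0))
        assert np.allclose(probs, 0.5)

    def test_matches_normal_cdf_oracle(self):
        values = np.array([-1.0, 0.0, 1.0])  # already z-scored up to scale
        probs = ts.standardize_factor(values)
        z = (values - values.mean()) / values.std()
        assert np.allclose(probs, norm.cdf(z), atol=1e-12)
        assert np.allclose(probs[1], 0.5)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=30, unique=True))
    def test_output_ordering_equals_input_ordering(self, values):
        values = np.array(values)
        probs = ts.standardize_factor(values)
        order = np.argsort(values, kind="stable")
        assert np.all(np.diff(probs[order]) >= 0)
        assert np.all((probs > 0) & (probs < 1))

    def test_constant_factor_rejected_when_handling_disabled(self):
        with pytest.raises(ValueError):
            ts.standardize_factor(np.ones(4), allow_constant=False)


class TestEquilibrateNormal:
    def test_no_movement_fixed_point_from_zero(self, chain_connectome):
        params = SIRGlobalParams(stay_probability=1.0, synthesis_rate0=0.2,
                                 clearance_rate0=0.05, n_steps=10)
        n, E = ts.equilibrate_normal(chain_connectome, params)
        assert np.allclose(n, 0.2 / 0.05, rtol=1e-8)
        assert np.all(E == 0)

    def test_synthesis_modulation_orders_steady_state(self, chain_connectome):
        params = SIRGlobalParams(stay_probability=1.0, synthesis_rate0=0.2,
                                 clearance_rate0=0.05)
        P = np.array([0.2, 0.5, 0.8])
        mod = ts.RegionalModulation(P, "synthesis")
        n, _ = ts.equilibrate_normal(chain_connectome, params, mod)
        assert n[0] < n[1] < n[2]

    def test_requires_positive_clearance(self, chain_connectome):
        with pytest.raises(ValueError):
            ts.equilibrate_normal(chain_connectome, SIRGlobalParams(clearance_rate0=0.0))


class TestSimulate:
    def test_isolated_regions_keep_seed(self):
        conn = ts.Connectome(np.zeros((4, 4)), list("abcd"))
        params = SIRGlobalParams(n_steps=50, synthesis_rate0=0.0, clearance_rate0=0.0)
        traj = ts.simulate(conn, 2, params)
        assert np.all(traj.misfolded[:, 2] == 1.0)
        assert np.all(traj.misfolded[:, [0, 1, 3]] == 0.0)

    def test_stay_probability_one_ignores_weights(self, chain_connectome):
        params = SIRGlobalParams(stay_probability=1.0, n_steps=100)
        other = ts.Connectome(chain_connectome.weights * 7.3, ["A", "B", "C"])
        t1 = ts.simulate(chain_connectome, 0, params)
        t2 = ts.simulate(other, 0, params)
        assert np.array_equal(t1.misfolded, t2.misfolded)
        assert np.array_equal(t1.normal, t2.normal)

    def test_chain_matches_naive_recurrence_exactly(self, chain_connectome):
        params = SIRGlobalParams(stay_probability=0.4, transfer_rate=0.8, velocity=0.3,
                                 synthesis_rate0=0.07, clearance_rate0=0.02, n_steps=6)
        P = np.array([0.3, 0.6, 0.9])
        for target in (None, "spread", "synthesis", "clearance", "misfold"):
            mod = ts.RegionalModulation(P, target) if target else None
            n0, En0 = ts.equilibrate_normal(chain_connectome, params, mod)
            traj = ts.simulate(chain_connectome, 1, params, mod)
            L = chain_connectome.edge_lengths()
            hn, hm = naive_sir(chain_connectome.weights, L, 1, params, P=P,
                               target=target, n_steps=6, n0=n0, En0=En0)
            assert np.allclose(traj.normal, hn, atol=1e-13), target
            assert np.allclose(traj.misfolded, hm, atol=1e-13), target

    def test_mass_conserved_without_synthesis_or_clearance(self, small_connectome):
        params = SIRGlobalParams(synthesis_rate0=0.0, clearance_rate0=0.0, n_steps=2000)
        traj = ts.simulate(small_connectome, 0, params)
        drift = np.abs(traj.total_mass - traj.total_mass[0]) / traj.total_mass[0]
        assert drift.max() < 1e-10

    def test_cumulative_misfolded_nondecreasing_without_clearance(self, small_connectome):
        params = SIRGlobalParams(synthesis_rate0=0.0, clearance_rate0=0.0, n_steps=500)
        traj = ts.simulate(small_connectome, 0, params)
        assert np.all(np.diff(traj.misfolded_mass) >= -1e-12)

    def test_unreachable_region_never_infected(self):
        # two components: {0,1} connected, {2,3} connected; seed in 0
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        conn = ts.Connectome(W, list("abcd"))
        traj = ts.simulate(conn, 0, SIRGlobalParams(n_steps=500))
        assert np.all(traj.misfolded[:, 2:] == 0.0)

    def test_misfold_modulation_monotone(self, chain_connectome):
        params = SIRGlobalParams(n_steps=200)
        lo = ts.RegionalModulation(np.array([0.5, 0.5, 0.2]), "misfold")
        hi = ts.RegionalModulation(np.array([0.5, 0.5, 0.8]), "misfold")
        t_lo = ts.simulate(chain_connectome, 0, params, lo)
        t_hi = ts.simulate(chain_connectome, 0, params, hi)
        assert np.all(t_hi.misfolded[:, 2] >= t_lo.misfolded[:, 2] - 1e-12)

    def test_bilateral_seed_split_equally(self, small_connectome):
        traj = ts.simulate(small_connectome, [0, 3], SIRGlobalParams(n_steps=2))
        assert traj.misfolded[0, 0] == traj.misfolded[0, 3] == 0.5

    def test_invalid_epicenter_rejected(self, chain_connectome):
        with pytest.raises(ValueError):
            _resolve_epicenter(chain_connectome, 5)


class TestExtractPattern:
    def test_step0_density_nonzero_only_at_epicenter(self, small_connectome):
        traj = ts.simulate(small_connectome, 4, SIRGlobalParams(n_steps=5))
        p = ts.extract_pattern(traj, 0)
        assert p[4] > 0 and np.all(np.delete(p, 4) == 0)

    def test_density_mode_is_trajectory_row(self, small_connectome):
        traj = ts.simulate(small_connectome, 0, SIRGlobalParams(n_steps=5))
        assert np.array_equal(ts.extract_pattern(traj, 3), traj.misfolded[3])

    def test_fraction_mode_zero_convention(self):
        conn = ts.Connectome(np.zeros((3, 3)), list("abc"))
        params = SIRGlobalParams(n_steps=3, synthesis_rate0=0.0, clearance_rate0=0.0)
        traj = ts.simulate(conn, 0, params)
        frac = ts.extract_pattern(traj, 2, "misfolded_fraction")
        assert frac[0] == 1.0  # all misfolded at the seeded region
        assert np.all(frac[1:] == 0.0)  # 0/0 regions return 0


class TestAgentOracle:
    def test_density_engine_matches_agent_simulation(self, rng):
        """Stochastic agent runs bracket the deterministic densities."""
        spec = ts.SyntheticSpec(n_regions=5, seed=21, epicenter_index=0)
        conn = ts.generate_connectome(ts.SyntheticSpec(n_regions=5, seed=21,
                                                       connectome_kind="dense"))
        params = SIRGlobalParams(stay_probability=0.7, transfer_rate=0.5, velocity=0.8,
                                 n_steps=60, synthesis_rate0=0.1, clearance_rate0=0.1)
        traj = ts.simulate(conn, 0, params)
        steps = [10, 50]
        reps = [ts.simulate_agents(conn, 0, params, agents_per_density=4000,
                                   rng=np.random.default_rng(1000 + k),
                                   record_steps=steps) for k in range(8)]
        for t in steps:
            samples = np.array([r[t] for r in reps])
            mean = samples.mean(axis=0)
            se = samples.std(axis=0, ddof=1) / np.sqrt(len(reps))
            z = np.abs(traj.misfolded[t] - mean) / np.maximum(se, 1e-6)
            assert np.max(z) < 4.0, (t, z)
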