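import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

import tauspread as ts
from tauspread.quantify import (
    CohortTauTable,
    _fit_two_gaussians,
    posterior_high_component,
)


def make_table(values, n_ref):
    values = np.asarray(values, float)
    n, r = values.shape
    return CohortTauTable(
        values,
        [f"p{i}" for i in range(n)],
        ["reference"] * n_ref + ["positive"] * (n - n_ref),
        [f"reg{j}" for j in range(r)],
    )


class TestCohortTable:
    def test_rejects_nonpositive_values_and_missing_reference(self):
        with pytest.raises(ValueError):
            make_table([[1.0], [0.0]], 1)
        with pytest.raises(ValueError):
            CohortTauTable(np.ones((2, 1)), ["a", "b"], ["positive", "positive"], ["r"])

    def test_tsv_roundtrip(self, tmp_path):
        tab = make_table([[1.0, 2.0], [1.5, 2.5], [3.0, 4.0]], 2)
        tab.write_tsv(tmp_path / "cohort.tsv")
        back = CohortTauTable.read_tsv(tmp_path / "cohort.tsv")
        assert back.group_labels == tab.group_labels
        assert np.allclose(back.values, tab.values)


class TestMinMaxLoad:
    def test_reference_extremes_map_to_zero_and_one(self):
        tab = make_table([[1.0], [3.0], [2.5]], 2)
        load = ts.minmax_normalize_load(tab)
        assert load[0, 0] == 0.0 and load[1, 0] == 1.0
        assert np.isclose(load[2, 0], 0.75)

    def test_hand_computed_interior_point(self):
        # reference values {1, 2, 3}; a query of 2.5 lands at 0.75
        tab = make_table([[1.0], [2.0], [3.0], [2.5]], 3)
        assert np.isclose(ts.minmax_normalize_load(tab)[3, 0], 0.75)

    def test_sub_reference_values_clipped_to_zero(self):
        tab = make_table([[1.0], [2.0], [0.5]], 2)
        assert ts.minmax_normalize_load(tab)[2, 0] == 0.0

    def test_positive_participants_may_exceed_one(self):
        tab = make_table([[1.0], [2.0], [5.0]], 2)
        assert ts.minmax_normalize_load(tab)[2, 0] == 4.0

    def test_zero_reference_range_names_region(self):
        tab = make_table([[1.0, 1.0], [2.0, 1.0], [1.5, 2.0]], 2)
        with pytest.raises(ts.DegenerateReferenceError, match="reg1"):
            ts.minmax_normalize_load(tab)

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    def test_equivariance_under_joint_affine_transform(self, scale, shift):
        """Jointly rescaling a region's values (reference included) leaves load unchanged."""
        rng = np.random.default_rng(0)
        base = rng.uniform(1.0, 3.0, size=(20, 1))
        tab = make_table(base, 8)
        shifted = make_table(base * scale + shift + 10.0, 8)  # keep values positive
        assert np.allclose(
            ts.minmax_normalize_load(tab), ts.minmax_normalize_load(shifted), atol=1e-9
        )


class TestTwoGaussianFit:
    def test_recovers_well_separated_components(self, rng):
        x = np.concatenate([rng.normal(1.0, 0.1, 300), rng.normal(2.5, 0.1, 200)])
        w, mu, sd = _fit_two_gaussians(x)
        assert np.allclose(mu, [1.0, 2.5], atol=0.03)
        assert np.allclose(w, [0.6, 0.4], atol=0.05)
        # closed-form Bayes posterior oracle at the true parameters
        tpp = posterior_high_component(np.array([1.0, 2.5]), w, mu, sd)
        assert tpp[0] < 0.01 and tpp[1] > 0.99

    def test_agrees_with_sklearn_on_bimodal_data(self, rng):
        sklearn = pytest.importorskip("sklearn.mixture")
        x = np.concatenate([rng.normal(1.1, 0.12, 250), rng.normal(2.0, 0.2, 150)])
        w, mu, sd = _fit_two_gaussians(x)
        g = sklearn.GaussianMixture(2, n_init=5, random_state=0).fit(x.reshape(-1, 1))
        order = np.argsort(g.means_.ravel())
        assert np.allclose(mu, g.means_.ravel()[order], atol=0.02)
        assert np.allclose(sd, np.sqrt(g.covariances_.ravel()[order]), atol=0.02)

    def test_posterior_crossing_point_is_half(self, rng):
        x = np.concatenate([rng.normal(1.0, 0.1, 200), rng.normal(2.0, 0.1, 200)])
        w, mu, sd = _fit_two_gaussians(x)
        # solve for the equal-posterior point on a fine grid and check 0.5
        grid = np.linspace(mu[0], mu[1], 20001)
        post = posterior_high_component(grid, w, mu, sd)
        crossing = grid[np.argmin(np.abs(post - 0.5))]
        assert abs(posterior_high_component(np.array([crossing]), w, mu, sd)[0] - 0.5) < 1e-3

    def test_equal_variance_posterior_is_monotone(self):
        w = np.array([0.5, 0.5])
        mu = np.array([1.0, 2.0])
        sd = np.array([0.15, 0.15])
        x = np.linspace(0.0, 3.0, 500)
        post = posterior_high_component(x, w, mu, sd)
        assert np.all(np.diff(post) >= 0)

    def test_zero_variance_sample_rejected(self):
        with pytest.raises(ValueError):
            _fit_two_gaussians(np.full(50, 2.0))


class TestFitTPP:
    def test_tpp_bounds_and_complement(self, default_cohort):
        _, _, table, _ = default_cohort
        tpp, params = ts.fit_tpp(table)
        assert np.all((tpp >= 0) & (tpp <= 1))
        # posterior of the lower component is the complement
        j = 0
        w = params.loc[j, ["w_low", "w_high"]].to_numpy(float)
        mu = params.loc[j, ["mu_low", "mu_high"]].to_numpy(float)
        sd = params.loc[j, ["sd_low", "sd_high"]].to_numpy(float)
        x = table.values[:, j]
        low = np.exp(
            np.log(w[0]) + norm.logpdf(x, mu[0], sd[0])
            - np.logaddexp(np.log(w[0]) + norm.logpdf(x, mu[0], sd[0]),
                           np.log(w[1]) + norm.logpdf(x, mu[1], sd[1]))
        )
        assert np.allclose(tpp[:, j] + low, 1.0, atol=1e-10)

    def test_component_weights_sum_to_one_and_means_ordered(self, default_cohort):
        _, _, table, _ = default_cohort
        _, params = ts.fit_tpp(table)
        assert np.allclose(params.w_low + params.w_high, 1.0)
        assert np.all(params.mu_low <= params.mu_high)

    def test_minimum_cohort_size_enforced(self):
        tab = make_table(np.linspace(1, 2, 8).reshape(4, 2), 2)
        with pytest.raises(ValueError):
            ts.fit_tpp(tab)


class TestGroupAverageAndBraak:
    def test_single_participant_average_is_identity(self):
        m = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert np.array_equal(ts.group_average_map(m, [1]), m[1])

    def test_two_participant_average(self):
        m = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert np.allclose(ts.group_average_map(m, [0, 1]), [2.0, 3.0])

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            ts.group_average_map(np.ones((3, 2)), np.zeros(3, dtype=bool))

    def test_braak_stage_means_and_sem(self):
        labels = ["a", "b", "c", "d"]
        assignment = {"a": "I", "b": "I", "c": "II", "d": "unassigned"}
        df, rho = ts.braak_summary(np.array([1.0, 3.0, 2.0, 9.0]), labels, assignment)
        stage1 = df[df.stage == "I"].iloc[0]
        # sample sd of {1, 3} is sqrt(2); SEM = sqrt(2)/sqrt(2) = 1
        assert stage1["mean"] == 2.0 and stage1["sem"] == 1.0 and stage1["n"] == 2
        stage2 = df[df.stage == "II"].iloc[0]
        assert stage2["mean"] == 2.0 and stage2["sem"] == 0.0  # single region
        assert np.isnan(df[df.stage == "VI"].iloc[0]["mean"])  # empty stage

    def test_constant_map_gives_zero_sems_and_no_trend(self):
        labels = [f"r{i}" for i in range(6)]
        assignment = {l: s for l, s in zip(labels, ["I", "I", "II", "II", "III", "III"])}
        df, rho = ts.braak_summary(np.full(6, 2.0), labels, assignment)
        present = df.dropna(subset=["mean"])
        assert np.all(present["sem"] == 0.0) and np.all(present["mean"] == 2.0)
        assert np.isnan(rho)


class TestLabelRecovery:
    def test_tpp_threshold_tracks_bayes_optimal_rule(self, default_cohort):
        """TPP>0.5 recovers the generator's latent labels nearly as well as the
        Bayes rule built from the true generative mixture."""
        _, _, table, truth = default_cohort
        tpp, _ = ts.fit_tpp(table)
        calls_bayes, labels = truth.bayes_classify(table, threshold_frac=0.5)
        acc_bayes = (calls_bayes == labels).mean()
        acc_tpp = ((tpp > 0.5) == labels).mean()
        assert acc_bayes - acc_tpp <= 0.02
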