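"""tICA, Markov-state models, PCCA+, CK test and free-energy surfaces.

Oracles: brute-force covariance loops, closed-form 2-state chains,
matrix-power stationarity, direct chain simulation for MFPTs, and exact
two-delta histograms for free energies.
"""

import numpy as np
import pytest

import abmsm as ab
from abmsm.kinetics import KB_KCAL_PER_MOL_K, MacrostateModel


# ---------------------------------------------------------------------------
# tICA
# ---------------------------------------------------------------------------

def _ar1(n, rho, rng):
    x = np.empty(n)
    x[0] = rng.normal()
    innov = rng.normal(size=n) * np.sqrt(1 - rho**2)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i]
    return x


def _mixed_ar1(n=100_000, rho_slow=0.99, rho_fast=0.5, seed=0):
    rng = np.random.default_rng(seed)
    slow, fast = _ar1(n, rho_slow, rng), _ar1(n, rho_fast, rng)
    mix = np.array([[0.6, 0.8], [-0.8, 0.6]])
    return np.column_stack([slow, fast]) @ mix.T, slow


class TestTICA:
    def test_leading_eigenvalue_matches_ar1_autocorrelation(self):
        data, _ = _mixed_ar1()
        model = ab.fit_tica(data, lag=1)
        assert model.eigenvalues[0] == pytest.approx(0.99, abs=0.01)

    def test_leading_component_unmixes_slow_process(self):
        data, slow = _mixed_ar1()
        model = ab.fit_tica(data, lag=1)
        proj = ab.project(model, data, n_components=1)[:, 0]
        corr = abs(np.corrcoef(proj, slow)[0, 1])
        assert corr > 0.99

    def test_covariances_match_bruteforce_loops(self):
        """Symmetrized per-segment estimator vs explicit loops."""
        rng = np.random.default_rng(1)
        segs = [rng.normal(size=(40, 3)), rng.normal(size=(25, 3))]
        lag = 4
        model = ab.fit_tica(segs, lag=lag)
        xs, ys = [], []
        for seg in segs:
            for t in range(seg.shape[0] - lag):
                xs.append(seg[t])
                ys.append(seg[t + lag])
        xs, ys = np.array(xs), np.array(ys)
        both = np.vstack([xs, ys])
        mean = both.mean(axis=0)
        c0 = (both - mean).T @ (both - mean) / both.shape[0]
        xc, yc = xs - mean, ys - mean
        ct = (xc.T @ yc + yc.T @ xc) / (2 * xs.shape[0])
        np.testing.assert_allclose(model.mean, mean, atol=1e-12)
        np.testing.assert_allclose(model.c0, c0, atol=1e-12)
        np.testing.assert_allclose(model.ct, (ct + ct.T) / 2, atol=1e-12)

    def test_no_pairs_straddle_segments(self):
        """Fitting [a, b] must equal pooling the per-segment moments, not
        fitting the naive concatenation."""
        rng = np.random.default_rng(2)
        a = rng.normal(size=(30, 2))
        b = rng.normal(size=(30, 2)) + 100.0  # huge jump at the boundary
        split = ab.fit_tica([a, b], lag=2)
        joined = ab.fit_tica(np.vstack([a, b]), lag=2)
        assert not np.allclose(split.ct, joined.ct)

    def test_eigenvectors_c0_orthonormal(self):
        data, _ = _mixed_ar1(n=20_000, seed=3)
        model = ab.fit_tica(data, lag=2)
        v = model.eigenvectors
        gram = v.T @ (model.c0 + model.ridge * np.eye(2)) @ v
        np.testing.assert_allclose(gram, np.eye(2), atol=1e-8)

    def test_kinetic_variance_cut(self):
        model = ab.fit_tica(_mixed_ar1(n=50_000, seed=4)[0], lag=1)
        m = model.n_components_for_kinetic_variance(0.95)
        lam2 = np.clip(model.eigenvalues, 0, None) ** 2
        assert lam2[:m].sum() / lam2.sum() >= 0.95
        if m > 1:
            assert lam2[:m - 1].sum() / lam2.sum() < 0.95

    def test_projection_is_mean_free(self):
        data, _ = _mixed_ar1(n=10_000, seed=5)
        model = ab.fit_tica(data, lag=1)
        proj = ab.project(model, data)
        np.testing.assert_allclose(proj.mean(axis=0), 0.0, atol=0.05)

    def test_errors(self):
        data = np.random.default_rng(0).normal(size=(50, 2))
        with pytest.raises(ValueError, match="lag"):
            ab.fit_tica(data, lag=0)
        with pytest.raises(ValueError, match="shorter than lag"):
            ab.fit_tica(data, lag=50)
        model = ab.fit_tica(data, lag=1)
        with pytest.raises(ValueError, match="dimension"):
            ab.project(model, np.zeros((5, 3)))


# ---------------------------------------------------------------------------
# Microstates
# ---------------------------------------------------------------------------

class TestKMeansMicrostates:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        truth = rng.integers(0, 3, size=600)
        coords = centers[truth] + rng.normal(scale=0.3, size=(600, 2))
        micro = ab.kmeans_microstates(coords, k=3, seed=0)
        # each true blob maps to exactly one label and labels are distinct
        mapped = {tuple(np.unique(micro.labels[truth == b])) for b in range(3)}
        assert all(len(m) == 1 for m in mapped)
        assert len(mapped) == 3

    def test_seed_determinism(self):
        coords = np.random.default_rng(1).normal(size=(500, 2))
        a = ab.kmeans_microstates(coords, k=20, seed=42)
        b = ab.kmeans_microstates(coords, k=20, seed=42)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_allclose(a.centers, b.centers)

    def test_segment_splitting(self):
        rng = np.random.default_rng(2)
        segs = [rng.normal(size=(120, 2)), rng.normal(size=(80, 2))]
        micro = ab.kmeans_microstates(segs, k=10, seed=0)
        assert [len(d) for d in micro.dtrajs] == [120, 80]
        np.testing.assert_array_equal(micro.labels,
                                      np.concatenate(micro.dtrajs))

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="< k"):
            ab.kmeans_microstates(np.zeros((5, 2)), k=10)


# ---------------------------------------------------------------------------
# Count matrix / MSM estimation
# ---------------------------------------------------------------------------

class TestCountMatrix:
    def test_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 4, size=200)
        for lag in (1, 3, 7):
            c = ab.count_matrix(d, lag)
            oracle = np.zeros((4, 4))
            for t in range(len(d) - lag):
                oracle[d[t], d[t + lag]] += 1
            np.testing.assert_array_equal(c, oracle)

    def test_multiple_segments_sum(self):
        d1 = np.array([0, 1, 0, 1])
        d2 = np.array([1, 1, 1])
        c = ab.count_matrix([d1, d2], 1)
        np.testing.assert_array_equal(c, [[0, 2], [1, 2]])

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError, match="shorter than lag"):
            ab.count_matrix(np.array([0, 1]), 5)


class TestEstimateMSM:
    def test_reversible_detailed_balance(self, small_hmm_result):
        d = small_hmm_result.hidden["shared"]
        model = ab.estimate_msm(ab.count_matrix(d, 1), lag=1)
        t, pi = model.transition_matrix, model.stationary_distribution
        np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(pi[:, None] * t, (pi[:, None] * t).T,
                                   atol=1e-10)
        np.testing.assert_allclose(pi @ t, pi, atol=1e-10)

    def test_symmetric_counts_reduce_to_naive(self):
        c = np.array([[50.0, 5.0, 2.0],
                      [5.0, 80.0, 4.0],
                      [2.0, 4.0, 60.0]])
        rev = ab.estimate_msm(c, reversible=True)
        naive = ab.estimate_msm(c, reversible=False)
        np.testing.assert_allclose(rev.transition_matrix,
                                   naive.transition_matrix, atol=1e-9)

    def test_stationary_distribution_matches_matrix_power(self):
        t = ab.metastable_transition_matrix(
            (0.4, 0.35, 0.25), np.array([[0, 2.0, 1.0], [2.0, 0, 3.0],
                                         [1.0, 3.0, 0]]), 0.01)
        pi = ab.stationary_distribution(t)
        powered = np.linalg.matrix_power(t, 4000)
        for row in powered:
            np.testing.assert_allclose(row, pi, atol=1e-10)

    def test_connected_set_restriction(self):
        # state 2 only receives, state 3 isolated: strong CC is {0, 1}
        c = np.array([[10.0, 5.0, 1.0, 0.0],
                      [6.0, 20.0, 0.0, 0.0],
                      [0.0, 0.0, 3.0, 0.0],
                      [0.0, 0.0, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="connected set"):
            model = ab.estimate_msm(c)
        np.testing.assert_array_equal(model.active_set, [0, 1])
        assert model.fraction_states == pytest.approx(0.5)
        assert model.fraction_counts == pytest.approx(41.0 / 45.0)
        mapped = model.map_labels(np.array([0, 1, 2, 3]))
        np.testing.assert_array_equal(mapped, [0, 1, -1, -1])

    def test_recovers_generating_matrix(self):
        t_true = ab.metastable_transition_matrix(
            (0.5, 0.3, 0.2), np.array([[0, 4.0, 1.0], [4.0, 0, 2.0],
                                       [1.0, 2.0, 0]]), 0.02)
        rng = np.random.default_rng(8)
        d = ab.sample_markov_chain(t_true, 200_000, rng)
        model = ab.estimate_msm(ab.count_matrix(d, 1), lag=1)
        np.testing.assert_allclose(model.transition_matrix, t_true, atol=0.01)
        np.testing.assert_allclose(model.stationary_distribution,
                                   (0.5, 0.3, 0.2), atol=0.01)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError, match="square"):
            ab.estimate_msm(np.zeros((2, 3)))
        with pytest.raises(ValueError, match="non-negative"):
            ab.estimate_msm(np.array([[1.0, -1.0], [1.0, 1.0]]))


class TestImpliedTimescales:
    def test_two_state_closed_form(self):
        a, b = 0.03, 0.07
        t = np.array([[1 - a, a], [b, 1 - b]])
        for lag in (1, 5):
            ts = ab.implied_timescales(np.linalg.matrix_power(t, lag), lag=lag)
            assert ts[0] == pytest.approx(-lag / np.log((1 - a - b) ** lag))
            assert ts[0] == pytest.approx(-1.0 / np.log(1 - a - b))

    def test_lag_invariance_for_markovian_matrix(self):
        t = ab.metastable_transition_matrix(
            (0.35, 0.30, 0.20, 0.15),
            np.array([[0, 6.0, 2, 1], [6, 0, 4, 2], [2, 4, 0, 5],
                      [1, 2, 5, 0]]), 5e-4)
        ts1 = ab.implied_timescales(t, lag=1)
        ts5 = ab.implied_timescales(np.linalg.matrix_power(t, 5), lag=5)
        np.testing.assert_allclose(ts1, ts5, rtol=1e-9)

    def test_negative_eigenvalue_excluded_with_warning(self):
        t = np.array([[0.1, 0.9], [0.9, 0.1]])
        with pytest.warns(UserWarning, match="below resolution"):
            ts = ab.implied_timescales(t, lag=1)
        assert len(ts) == 0

    def test_unit_eigenvalue_gives_inf(self):
        assert np.isinf(ab.implied_timescales(np.eye(2), lag=1))[0]

    def test_model_input_uses_model_lag(self, small_hmm_result):
        d = small_hmm_result.hidden["shared"]
        model = ab.estimate_msm(ab.count_matrix(d, 5), lag=5)
        ts = ab.implied_timescales(model, n=1)
        # slowest relaxation of the generating chain: -1/ln(lambda_2)
        lam = np.sort(np.linalg.eigvals(
            small_hmm_result.spec.transition_matrix).real)[::-1]
        true_t2 = -1.0 / np.log(lam[1])
        assert ts[0] == pytest.approx(true_t2, rel=0.2)

    def test_bare_matrix_requires_lag(self):
        with pytest.raises(ValueError, match="lag"):
            ab.implied_timescales(np.eye(3))


# ---------------------------------------------------------------------------
# PCCA+ and macrostate kinetics
# ---------------------------------------------------------------------------

def _block_chain(n_blocks=3, per_block=3, fast=0.2, slow=1e-3, seed=0):
    """Metastable chain of n_blocks blocks with fast intra-block mixing."""
    n = n_blocks * per_block
    exchange = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = i // per_block == j // per_block
            exchange[i, j] = exchange[j, i] = fast if same else slow
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.8, 1.2, size=n)
    w /= w.sum()
    scale = 0.9 * (w / exchange.sum(axis=1)).min()
    return ab.metastable_transition_matrix(w, exchange, scale), w


class TestPCCA:
    def test_recovers_metastable_blocks(self):
        t, w = _block_chain()
        model = ab.estimate_msm(np.diag(w) @ t * 1e6, reversible=True)
        macro = ab.pcca(model, 3)
        blocks = [macro.assignments[k * 3:(k + 1) * 3] for k in range(3)]
        assert all(len(set(b)) == 1 for b in blocks)
        assert len({b[0] for b in blocks}) == 3

    def test_memberships_are_stochastic(self):
        t, w = _block_chain(seed=1)
        model = ab.estimate_msm(np.diag(w) @ t * 1e6, reversible=True)
        macro = ab.pcca(model, 3)
        np.testing.assert_allclose(macro.memberships.sum(axis=1), 1.0,
                                   atol=1e-10)
        assert np.all(macro.memberships >= 0)

    def test_probabilities_match_block_weights_descending(self):
        t, w = _block_chain(seed=2)
        model = ab.estimate_msm(np.diag(w) @ t * 1e6, reversible=True)
        macro = ab.pcca(model, 3)
        block_w = np.array([w[k * 3:(k + 1) * 3].sum() for k in range(3)])
        np.testing.assert_allclose(macro.probabilities,
                                   np.sort(block_w)[::-1], atol=1e-3)
        assert np.all(np.diff(macro.probabilities) <= 1e-12)

    def test_too_many_macrostates_rejected(self):
        c = np.array([[50.0, 5.0], [5.0, 50.0]])
        model = ab.estimate_msm(c)
        with pytest.raises(ValueError, match="smaller number"):
            ab.pcca(model, 3)
        with pytest.raises(ValueError, match="at least 2"):
            ab.pcca(model, 1)


class TestMacrostateKinetics:
    @staticmethod
    def _two_state_model(a, b, lag=1):
        t = np.array([[1 - a, a], [b, 1 - b]])
        pi = np.array([b, a]) / (a + b)
        model = ab.MarkovModel(
            lag=lag, counts=t, transition_matrix=t,
            stationary_distribution=pi, active_set=np.arange(2),
            fraction_states=1.0, fraction_counts=1.0, reversible=True,
        )
        macro = MacrostateModel(
            memberships=np.eye(2), assignments=np.array([0, 1]),
            probabilities=pi, n_macrostates=2,
        )
        return model, macro

    def test_two_state_closed_form(self):
        a, b = 0.02, 0.05
        model, macro = self._two_state_model(a, b)
        mfpt, probs = ab.macrostate_kinetics(model, macro)
        assert mfpt[0, 1] == pytest.approx(1.0 / a)  # geometric waiting time
        assert mfpt[1, 0] == pytest.approx(1.0 / b)
        assert mfpt[0, 0] == 0.0 and mfpt[1, 1] == 0.0

    def test_lag_scales_times(self):
        model, macro = self._two_state_model(0.02, 0.05, lag=10)
        mfpt, _ = ab.macrostate_kinetics(model, macro)
        assert mfpt[0, 1] == pytest.approx(10.0 / 0.02)

    def test_matches_direct_simulation(self):
        a, b = 0.02, 0.05
        model, macro = self._two_state_model(a, b)
        mfpt, _ = ab.macrostate_kinetics(model, macro)
        rng = np.random.default_rng(4)
        d = ab.sample_markov_chain(model.transition_matrix, 400_000, rng)
        # empirical mean passage 0 -> 1: time to next 1 after each 0-entry
        entries = np.nonzero((d[1:] == 0) & (d[:-1] == 1))[0] + 1
        times = []
        ones = np.nonzero(d == 1)[0]
        for e in entries[:-1]:
            nxt = ones[np.searchsorted(ones, e)]
            times.append(nxt - e)
        assert np.mean(times) == pytest.approx(mfpt[0, 1], rel=0.1)


# ---------------------------------------------------------------------------
# Chapman-Kolmogorov test
# ---------------------------------------------------------------------------

class TestCKTest:
    def test_markovian_chain_passes(self, small_hmm_result):
        d = small_hmm_result.hidden["shared"]
        res = ab.ck_test(d, lag=5, n_macrostates=4)
        assert res.passed
        assert res.multiples == [1, 2, 3, 4, 5]
        assert res.predicted.shape == (5, 4, 4)
        np.testing.assert_allclose(res.predicted.sum(axis=2), 1.0, atol=1e-8)
        assert np.all(res.std_err >= 0)

    def test_non_markovian_control_fails(self):
        """Binarized double-well positions are strongly non-Markovian at
        lag 1: recrossings inflate the short-lag rates."""
        x = ab.simulate_double_well(barrier=2.0, n_steps=100_000, seed=0)
        d = (x > 0).astype(int)
        res = ab.ck_test(d, lag=1, n_macrostates=2, multiples=(1, 10, 50))
        assert not res.passed
        # systematic, growing deviation - not a borderline statistical miss
        assert res.max_deviation[-1] > 5 * res.max_deviation[0]

    def test_too_short_trajectory_rejected(self):
        d = np.random.default_rng(0).integers(0, 2, size=60)
        with pytest.raises(ValueError, match="multiple"):
            ab.ck_test(d, lag=20, n_macrostates=2, multiples=(1, 5))


# ---------------------------------------------------------------------------
# Free-energy surfaces
# ---------------------------------------------------------------------------

class TestFreeEnergySurface:
    def test_two_delta_exact(self):
        """Counts 300:100 in two bins: dG = kT ln 3 exactly."""
        coords = np.concatenate([np.full(300, 0.5), np.full(100, 2.5)])
        fes = ab.free_energy_surface(coords, bins=3, hist_range=(0.0, 3.0))
        kt = KB_KCAL_PER_MOL_K * 300.0
        assert fes.value_at(0.5) == pytest.approx(0.0)
        assert fes.value_at(2.5) == pytest.approx(kt * np.log(3.0))
        assert np.isinf(fes.value_at(1.5))  # empty middle bin
        assert fes.free_energy[np.isfinite(fes.free_energy)].min() == 0.0

    def test_weights_equivalent_to_replication(self):
        coords = np.array([0.5, 2.5])
        weighted = ab.free_energy_surface(coords, weights=np.array([3.0, 1.0]),
                                          bins=3, hist_range=(0, 3))
        replicated = ab.free_energy_surface(
            np.array([0.5] * 3 + [2.5]), bins=3, hist_range=(0, 3))
        np.testing.assert_allclose(weighted.free_energy,
                                   replicated.free_energy)

    def test_temperature_scaling(self):
        coords = np.concatenate([np.zeros(200), np.ones(100) * 2.5])
        f300 = ab.free_energy_surface(coords, bins=3, hist_range=(-0.5, 3.0),
                                      temperature=300.0)
        f600 = ab.free_energy_surface(coords, bins=3, hist_range=(-0.5, 3.0),
                                      temperature=600.0)
        assert f600.value_at(2.5) == pytest.approx(2 * f300.value_at(2.5))

    def test_2d_two_cluster_ratio(self):
        pts = np.vstack([np.tile([0.25, 0.25], (400, 1)),
                         np.tile([0.75, 0.75], (100, 1))])
        fes = ab.free_energy_surface(pts, bins=2, hist_range=[(0, 1), (0, 1)])
        kt = KB_KCAL_PER_MOL_K * 300.0
        assert fes.value_at((0.25, 0.25)) == pytest.approx(0.0)
        assert fes.value_at((0.75, 0.75)) == pytest.approx(kt * np.log(4.0))
        assert fes.free_energy.shape == (2, 2)

    def test_double_well_potential_shape(self):
        x = np.linspace(-1.5, 1.5, 301)
        u = ab.double_well_potential(x, barrier=2.0)
        assert u[150] == pytest.approx(2.0)  # x = 0
        assert ab.double_well_potential(1.0, 2.0) == pytest.approx(0.0)
        assert ab.double_well_potential(-1.0, 2.0) == pytest.approx(0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty|occupied"):
            ab.free_energy_surface(np.array([]))
        with pytest.raises(ValueError, match="1-D"):
            ab.free_energy_surface(np.zeros((5, 3)))
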