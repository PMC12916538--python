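import numpy as np
import pytest

from hstrend import (Grid, auc_rank, build_features, fit_maxent,
                     predict_suitability, run_species_year, hsi_series,
                     train_test_split_size, OccurrenceSet)
from hstrend.maxent import MaxentModel, FeatureSet
from tests.conftest import make_stack


@pytest.fixture
def env_stack(rng):
    """One informative continuous predictor + one constant + one binary."""
    g = Grid(20, 20, origin_y=20.0)
    n = g.n_cells
    x = rng.normal(size=n)
    return make_stack(g, [2001], {
        "x": {2001: x},
        "flat": {2001: np.full(n, 3.0)},
        "fire": {2001: (rng.random(n) < 0.3).astype(float)},
    })


class TestFeatures:
    def test_standardization_on_background(self, env_stack):
        bg = env_stack.grid.valid_cell_ids()
        fs = build_features(env_stack, 2001, bg)
        F = fs.matrix(bg)
        lin = fs.feature_names.index("x:lin")
        assert F[:, lin].mean() == pytest.approx(0.0, abs=1e-12)
        assert F[:, lin].std() == pytest.approx(1.0, abs=1e-12)

    def test_quadratic_is_square_of_linear(self, env_stack):
        bg = env_stack.grid.valid_cell_ids()
        fs = build_features(env_stack, 2001, bg)
        F = fs.matrix(bg)
        lin = fs.feature_names.index("x:lin")
        quad = fs.feature_names.index("x:quad")
        np.testing.assert_allclose(F[:, quad], F[:, lin] ** 2)

    def test_constant_predictor_excluded(self, env_stack):
        bg = env_stack.grid.valid_cell_ids()
        fs = build_features(env_stack, 2001, bg)
        assert "flat:lin" not in fs.feature_names
        assert "flat:lin" in fs.excluded

    def test_binary_predictor_linear_only(self, env_stack):
        bg = env_stack.grid.valid_cell_ids()
        fs = build_features(env_stack, 2001, bg)
        assert "fire:bin" in fs.feature_names
        assert "fire:quad" not in fs.feature_names

    def test_all_degenerate_is_hard_error(self, grid4x5):
        stack = make_stack(grid4x5, [2001], {"c": {2001: np.full(20, 1.0)}})
        with pytest.raises(ValueError, match="uninformative"):
            build_features(stack, 2001, grid4x5.valid_cell_ids())

    def test_clamping_limits_projection(self, env_stack):
        bg = np.arange(100)  # calibrate on a subset
        fs = build_features(env_stack, 2001, bg)
        F = fs.matrix(env_stack.grid.valid_cell_ids(), clamp=True)
        assert (F >= fs.clamp_lo - 1e-12).all()
        assert (F <= fs.clamp_hi + 1e-12).all()


class TestFit:
    def _fit(self, stack, presences, **kw):
        bg = stack.grid.valid_cell_ids()
        fs = build_features(stack, 2001, bg)
        return fs, fit_maxent(fs, presences, bg, **kw)

    def test_presences_at_high_values_give_positive_weight(self, env_stack):
        x = env_stack.layers[(2001, "x")].values
        presences = np.argsort(x)[-25:]
        fs, model = self._fit(env_stack, presences)
        assert model.lam[fs.feature_names.index("x:lin")] > 0

    def test_presences_equal_background_gives_uniform_model(self, env_stack):
        bg = env_stack.grid.valid_cell_ids()
        fs, model = self._fit(env_stack, bg)
        # maximum-entropy solution: nothing to distinguish, q uniform
        assert np.abs(model.lam).max() < 0.05
        q = model.raw_distribution()
        assert q.max() / q.min() < 1.5

    def test_infinite_regularization_zeroes_weights(self, env_stack):
        presences = np.arange(30)
        fs, model = self._fit(env_stack, presences, beta_multiplier=1e9)
        assert np.all(model.lam == 0.0)

    def test_kkt_moment_conditions(self, env_stack, rng):
        """|E_q f - mean_presence f| <= beta, with equality where lam != 0."""
        x = env_stack.layers[(2001, "x")].values
        presences = np.argsort(x)[-40:]
        fs, model = self._fit(env_stack, presences)
        bg = model.background
        Fp = fs.matrix(presences)
        q = model.raw_distribution()
        gap = q @ fs.matrix(bg) - Fp.mean(axis=0)
        tol = 1e-4
        assert (np.abs(gap) <= model.beta + tol).all()
        active = model.lam != 0
        np.testing.assert_allclose(np.abs(gap[active]), model.beta[active],
                                   atol=tol)

    def test_objective_nondecreasing_over_iterations(self, env_stack):
        x = env_stack.layers[(2001, "x")].values
        _, model = self._fit(env_stack, np.argsort(x)[-25:],
                             record_path=True)
        path = np.array(model.objective_path)
        assert (np.diff(path) >= -1e-10).all()

    def test_too_few_presences_rejected(self, env_stack):
        with pytest.raises(ValueError):
            self._fit(env_stack, np.array([3]))


class TestPredict:
    def test_unit_rate_zero_entropy_scores_half(self, grid4x5):
        # s = c r / (1 + c r) with c = e^H: r = 1, H = 0 -> 1/2
        fs = FeatureSet(grid4x5, ["f"], {"p": np.zeros(20)}, [("bin", "p")],
                        {}, clamp_lo=np.zeros(1), clamp_hi=np.zeros(1))
        model = MaxentModel(features=fs, lam=np.zeros(1), beta=np.zeros(1),
                            background=np.arange(1), log_z=0.0, entropy=0.0,
                            converged=True)
        out = predict_suitability(model, fs, cells=np.arange(1))
        assert out.values[0] == pytest.approx(0.5)

    def test_uniform_model_scores_constant(self, env_stack):
        bg = env_stack.grid.valid_cell_ids()
        fs = build_features(env_stack, 2001, bg)
        model = fit_maxent(fs, bg, bg)
        s = predict_suitability(model, fs).valid_values()
        assert s.std() < 0.05

    def test_suitability_monotone_in_linear_predictor_score(self, env_stack):
        x = env_stack.layers[(2001, "x")].values
        bg = env_stack.grid.valid_cell_ids()
        fs = build_features(env_stack, 2001, bg)
        model = fit_maxent(fs, np.argsort(x)[-30:], bg)
        s = predict_suitability(model, fs).valid_values()
        eta = fs.matrix(bg, clamp=True) @ model.lam
        order = np.argsort(eta)
        assert (np.diff(s[order]) >= -1e-12).all()

    def test_output_in_unit_interval(self, env_stack):
        x = env_stack.layers[(2001, "x")].values
        bg = env_stack.grid.valid_cell_ids()
        fs = build_features(env_stack, 2001, bg)
        model = fit_maxent(fs, np.argsort(x)[-20:], bg)
        s = predict_suitability(model, fs).valid_values()
        assert (s > 0).all() and (s <= 1).all()


class TestAuc:
    @pytest.mark.parametrize("pres,bg,expected", [
        ([0.9, 0.8], [0.1, 0.2], 1.0),
        ([0.5, 0.5], [0.5, 0.5], 0.5),
        ([0.8, 0.3], [0.5, 0.1], 0.75),
    ])
    def test_known_values(self, pres, bg, expected):
        assert auc_rank(pres, bg) == pytest.approx(expected)

    def test_matches_mann_whitney_u(self, rng):
        from scipy.stats import mannwhitneyu
        for _ in range(20):
            p = rng.normal(1, 1, size=rng.integers(5, 30))
            b = rng.normal(0, 1, size=rng.integers(5, 50))
            U = mannwhitneyu(p, b).statistic
            assert auc_rank(p, b) == pytest.approx(U / (len(p) * len(b)))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            auc_rank([], [0.5])


class TestReplicates:
    def test_seventy_thirty_split_sizes(self):
        assert train_test_split_size(20) == 14
        assert train_test_split_size(30) == 21
        assert train_test_split_size(15) == 11  # round-half-up of 10.5

    def test_replicates_deterministic_given_seed(self, env_stack):
        x = env_stack.layers[(2001, "x")].values
        sp = OccurrenceSet("sp", set(np.argsort(x)[-20:].tolist()))
        r1 = run_species_year(sp, env_stack, 2001, n_replicates=2, seed=7)
        r2 = run_species_year(sp, env_stack, 2001, n_replicates=2, seed=7)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.train_cells, b.train_cells)
            assert a.auc_test == b.auc_test

    def test_disjoint_split_and_sizes(self, env_stack):
        x = env_stack.layers[(2001, "x")].values
        sp = OccurrenceSet("sp", set(np.argsort(x)[-20:].tolist()))
        for r in run_species_year(sp, env_stack, 2001, n_replicates=3, seed=0):
            assert len(r.train_cells) == 14 and len(r.test_cells) == 6
            assert not set(r.train_cells) & set(r.test_cells)

    def test_informative_species_discriminates(self, env_stack):
        x = env_stack.layers[(2001, "x")].values
        sp = OccurrenceSet("tight", set(np.argsort(x)[-30:].tolist()))
        reps = run_species_year(sp, env_stack, 2001, n_replicates=5, seed=0)
        assert np.mean([r.auc_train for r in reps]) > 0.7

    def test_hsi_single_replicate_equals_prediction(self, env_stack):
        x = env_stack.layers[(2001, "x")].values
        sp = OccurrenceSet("sp", set(np.argsort(x)[-20:].tolist()))
        hsi = hsi_series(sp, env_stack, n_replicates=1, seed=3)
        rep = run_species_year(sp, env_stack, 2001, n_replicates=1, seed=3)[0]
        vid = env_stack.grid.valid_cell_ids()
        np.testing.assert_allclose(hsi.hsi[2001].values[vid],
                                   rep.suitability.values[vid])

    def test_hsi_bounded_in_unit_interval(self, env_stack):
        x = env_stack.layers[(2001, "x")].values
        sp = OccurrenceSet("sp", set(np.argsort(x)[-20:].tolist()))
        hsi = hsi_series(sp, env_stack, n_replicates=3, seed=3)
        v = hsi.hsi[2001].valid_values()
        assert (v >= 0).all() and (v <= 1).all()
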