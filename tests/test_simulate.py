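"""Mock-community simulator: closed forms, contracts and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gamnet import simulate


class TestSeasonalVector:
    @pytest.mark.parametrize(
        ("shape", "phase", "index", "expected"),
        [
            ("gradual", 0, 0, 1.0),  # cos(0) = 1
            ("gradual", 6, 0, 0.0),  # cos(pi) = -1
            ("gradual", 0, 6, 0.0),
            ("abrupt", 2, 0, 0.75**10),
            ("abrupt", 0, 0, 1.0),
            ("gradual", 3, 0, 0.5),
        ],
    )
    def test_closed_form(self, shape, phase, index, expected):
        s = simulate.seasonal_vector(shape, index + 1, phase_start=phase)
        assert s[index] == pytest.approx(expected, abs=1e-12)

    @given(phase=st.integers(0, 11), n=st.integers(13, 120))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_bounds_and_period(self, phase, n):
        s = simulate.seasonal_vector("gradual", n, phase)
        assert np.all(s >= -1e-12) and np.all(s <= 1.0 + 1e-12)
        assert np.allclose(s[:-12], s[12:], atol=1e-9)

    @given(phase=st.integers(0, 11))
    @settings(max_examples=12, deadline=None, derandomize=True)
    def test_abrupt_below_gradual(self, phase):
        g = simulate.seasonal_vector("gradual", 48, phase)
        a = simulate.seasonal_vector("abrupt", 48, phase)
        assert np.all(a <= g + 1e-12)

    def test_unknown_shape(self):
        with pytest.raises(ValueError):
            simulate.seasonal_vector("square", 10)


class TestGraphs:
    def test_er_trivial_probabilities(self):
        assert simulate.make_er_graph(3, 0.0, seed=0).sum() == 0
        full = simulate.make_er_graph(3, 1.0, seed=0)
        assert full.sum() == 6  # complete triangle, 3 undirected edges

    def test_er_expected_edge_count(self):
        # E[edges] = C(400,2) * 0.01 = 798; Monte-Carlo mean over 200 seeds
        counts = [simulate.make_er_graph(400, 0.01, seed=s).sum() / 2 for s in range(200)]
        expected = 400 * 399 / 2 * 0.01
        se = np.sqrt(expected * 0.99) / np.sqrt(200)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_er_symmetric_zero_diag(self):
        adj = simulate.make_er_graph(50, 0.1, seed=1)
        assert np.array_equal(adj, adj.T)
        assert np.all(np.diag(adj) == 0)

    def test_er_bad_probability(self):
        with pytest.raises(ValueError):
            simulate.make_er_graph(10, 1.5)

    def test_ba_tree_edge_count(self):
        assert simulate.make_ba_graph(100, seed=0).sum() / 2 == 99
        assert simulate.make_ba_graph(2, seed=0).sum() / 2 == 1

    def test_ba_heavy_tail(self):
        for seed in range(50):
            deg = simulate.make_ba_graph(400, seed=seed).sum(axis=1)
            assert deg.max() > np.median(deg)


class TestCovariance:
    def test_two_species_low(self):
        adj = np.array([[0, 1], [1, 0]])
        cov, loading = simulate.graph_to_covariance(adj, 10.0)
        assert cov[0, 1] == cov[1, 0] == 10.0
        assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_empty_graph_is_diagonal(self):
        cov, loading = simulate.graph_to_covariance(np.zeros((4, 4), dtype=int), 100.0)
        assert np.allclose(cov, np.diag(np.diag(cov)))
        assert loading == 0.0

    def test_er_high_level_pd(self):
        adj = simulate.make_er_graph(50, 0.01, seed=3)
        cov, _ = simulate.graph_to_covariance(adj, 100.0)
        assert np.linalg.eigvalsh(cov)[0] > 0

    def test_support_consistency(self):
        # nonzero off-diagonal covariance exactly where adjacency has an edge
        adj = simulate.make_er_graph(40, 0.05, seed=9)
        cov, _ = simulate.graph_to_covariance(adj, 10.0)
        off = cov.copy()
        np.fill_diagonal(off, 0.0)
        assert np.array_equal((off != 0).astype(int), adj)


class TestDrawAbundances:
    def test_mean_recovery(self):
        cov = np.diag([4.0, 9.0, 1.0])
        x = simulate.draw_abundances(cov, 10000, seed=0)
        rng = np.random.default_rng(0)
        mu = rng.normal(10.0, 1.0, size=3)
        se = np.sqrt(np.diag(cov) / 10000)
        assert np.all(np.abs(x.mean(axis=1) - mu) < 3 * se)

    def test_pairwise_correlation(self):
        cov = np.array([[25.0, 10.0], [10.0, 25.0]])
        x = simulate.draw_abundances(cov, 20000, seed=1)
        r = np.corrcoef(x)[0, 1]
        # analytic correlation 10/25 = 0.4; 3 SE via Fisher approximation
        se = (1 - 0.4**2) / np.sqrt(20000)
        assert abs(r - 0.4) < 3 * se

    def test_single_sample(self):
        x = simulate.draw_abundances(np.eye(3), 1, seed=2)
        assert x.shape == (3, 1) and np.all(np.isfinite(x))

    def test_non_pd_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            simulate.draw_abundances(bad, 10, seed=0)


class TestContamination:
    def test_seasonal_noop_when_unselected(self, rng):
        x = rng.normal(10, 1, size=(5, 36))
        out = simulate.apply_seasonal(x, [], "gradual", seed=0)
        assert np.array_equal(out, x)

    def test_seasonal_zeros_every_period(self):
        x = np.ones((1, 36))
        s = simulate.seasonal_vector("gradual", 36, phase_start=6)
        out = x * s
        assert out[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert out[0, 12] == pytest.approx(0.0, abs=1e-12)

    def test_seasonal_lag12_autocorrelation(self, rng):
        # contaminated rows must be more self-similar at lag 12 than at 5/7
        def autocorr(v, lag):
            v = v - v.mean()
            return float(v[:-lag] @ v[lag:] / (v @ v))

        acs = {5: [], 7: [], 12: []}
        for seed in range(10):
            x = simulate.draw_abundances(np.eye(6) * 25.0, 200, seed=seed) + 0.0
            out = simulate.apply_seasonal(x, range(6), "gradual", seed=seed)
            for row in out:
                for lag in acs:
                    acs[lag].append(autocorr(row, lag))
        assert np.mean(acs[12]) > np.mean(acs[5])
        assert np.mean(acs[12]) > np.mean(acs[7])

    def test_longterm_additive_closed_form(self):
        trend = simulate.longterm_vector(200, recursion_mode="additive", slope=0.01, sign=+1)
        assert trend[-1] == pytest.approx(0.01 + 199 * 0.01, abs=1e-12)
        assert np.all(np.diff(trend) > 0)

    def test_longterm_as_printed_fixed_point(self):
        trend = simulate.longterm_vector(200, recursion_mode="as_printed", slope=0.01, sign=+1)
        assert trend[-1] == pytest.approx(0.01 / (1 - 0.01), rel=1e-9)

    def test_longterm_single_point(self):
        assert simulate.longterm_vector(1, seed=0)[0] == pytest.approx(0.01)

    def test_apply_longterm_monotone(self):
        x = np.full((1, 100), 5.0)
        out = simulate.apply_longterm(x, [0], seed=7)
        diffs = np.diff(out[0])
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_apply_longterm_noop(self, rng):
        x = rng.normal(size=(4, 50))
        assert np.array_equal(simulate.apply_longterm(x, [], seed=0), x)


class TestCountTable:
    def test_symmetric_column(self):
        ct = simulate.to_count_table(np.array([[0.0], [0.0]]))
        assert np.allclose(ct.rel_abundance[:, 0], [0.5, 0.5])

    def test_exp_then_closure(self):
        ct = simulate.to_count_table(np.array([[np.log(2.0)], [0.0]]))
        assert np.allclose(ct.rel_abundance[:, 0], [2 / 3, 1 / 3])

    def test_columns_close_to_one(self, rng):
        x = rng.normal(10, 5, size=(30, 50))
        ct = simulate.to_count_table(x)
        assert np.allclose(ct.rel_abundance.sum(axis=0), 1.0, atol=1e-9)
        assert np.all(ct.rel_abundance >= 0)

    def test_month_predictor_cadence(self, rng):
        ct = simulate.to_count_table(rng.normal(size=(3, 30)))
        assert list(ct.day[:4]) == [1, 2, 3, 4]
        assert list(ct.month[:13]) == [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 1]

    def test_zero_inflation_count(self, rng):
        x = rng.normal(size=(100, 200))
        ct = simulate.to_count_table(x, zero_inflation_frac=0.3, seed=0)
        assert int((ct.rel_abundance == 0).sum()) == round(0.3 * 100 * 200)

    def test_all_zero_column_errors(self):
        x = np.zeros((2, 2))
        with pytest.raises(ValueError, match="cannot close"):
            simulate.to_count_table(x, zero_inflation_frac=0.8, seed=1)


class TestConditionGrid:
    def test_default_grid_size(self):
        conds = simulate.enumerate_conditions()
        assert len(conds) == 84
        assert len(conds) * 100 == 8400

    def test_restricted_grid(self):
        conds = simulate.enumerate_conditions(
            topologies=("er",), covariance_levels=("high",), longterm_fractions=(0.0,)
        )
        assert len(conds) == 7  # 1 no-seasonality + 2 shapes x 3 fractions

    def test_no_duplicate_conditions(self):
        conds = simulate.enumerate_conditions()
        assert len(set(conds)) == len(conds)

    def test_zero_seasonality_shape_collapsed(self):
        for c in simulate.enumerate_conditions():
            if c.seasonal_fraction == 0.0:
                assert c.seasonal_shape is None


class TestSimulateDataset:
    def _condition(self, **kw):
        defaults = dict(
            topology="er",
            covariance_level="low",
            seasonal_fraction=0.5,
            seasonal_shape="gradual",
            longterm_fraction=0.5,
            n_species=20,
            n_samples=48,
        )
        defaults.update(kw)
        return simulate.SimulationCondition(**defaults)

    def test_reproducibility(self):
        c = self._condition()
        d1 = simulate.simulate_dataset(c, seed=11)
        d2 = simulate.simulate_dataset(c, seed=11)
        assert np.array_equal(d1.latent, d2.latent)
        assert np.array_equal(d1.counts.rel_abundance, d2.counts.rel_abundance)
        assert np.array_equal(d1.truth.adjacency, d2.truth.adjacency)

    def test_selection_sizes(self):
        d = simulate.simulate_dataset(self._condition(), seed=3)
        assert len(d.seasonal_species) == 10
        assert len(d.longterm_species) == 10

    def test_user_topology_roundtrip(self):
        adj = simulate.make_er_graph(20, 0.1, seed=5)
        c = self._condition(topology="user_supplied")
        d = simulate.simulate_dataset(c, seed=4, user_adjacency=adj)
        assert np.array_equal(d.truth.adjacency, adj)

    def test_user_topology_requires_matrix(self):
        with pytest.raises(ValueError, match="user_adjacency"):
            simulate.simulate_dataset(self._condition(topology="user_supplied"), seed=0)
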