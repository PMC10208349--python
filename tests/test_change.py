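"""Area statistics, percent change, Markov estimation/projection, chi-squared."""

import numpy as np
import pytest

from tidemark import synthetic
from tidemark.change import (ClassProportions, TransitionMatrix, chi_square_validate,
                             class_areas, estimate_transition, percent_change,
                             project_markov, project_series,
                             stationary_distribution)
from tidemark.raster import ClassRaster, GridGeometry, RasterError

M_STICKY = np.array([[0.9, 0.1], [0.2, 0.8]])


def cmap(codes):
    arr = np.asarray(codes, dtype=np.uint8)
    return ClassRaster(arr, GridGeometry(*arr.shape))


class TestAreas:
    def test_pixel_count_times_009(self):
        big = ClassRaster(np.ones((100, 100), dtype=np.uint8),
                          GridGeometry(100, 100))
        a = class_areas(big)
        assert a.areas_ha[1] == pytest.approx(900.0)
        assert a.areas_ha[2] == 0.0

    def test_known_pixel_count(self):
        codes = np.full((40, 40), 2, dtype=np.uint8)
        codes.flat[:1234] = 1
        a = class_areas(cmap(codes))
        assert a.areas_ha[1] == pytest.approx(1234 * 0.09)
        assert a.areas_ha[1] == pytest.approx(111.06)

    def test_nodata_excluded(self):
        a = class_areas(cmap([[0, 1], [2, 0]]))
        assert a.pixel_counts == {1: 1, 2: 1}


class TestPercentChange:
    # observed regional mangrove areas at two dates -> signed percent change
    @pytest.mark.parametrize("s_i,s_j,pct,delta", [
        (2876.3, 5634.2, 95.88, 2757.9),    # decade of strong gain
        (1842.5, 1839.7, -0.15, -2.8),      # near-stable with slight loss
        (6738.1, 6601.8, -2.02, -136.3),
        (55302.4, 60033.8, 8.56, 4731.4),
    ])
    def test_signed_percent_and_delta(self, s_i, s_j, pct, delta):
        rec = percent_change(s_i, s_j)
        assert rec.percent == pytest.approx(pct, abs=0.005)
        assert rec.delta == pytest.approx(delta, abs=1e-9)
        assert rec.direction == ("gain" if delta > 0 else "loss")

    def test_no_change_is_zero_percent(self):
        rec = percent_change(100.0, 100.0)
        assert rec.percent == 0.0 and rec.direction == "stable"

    def test_zero_initial_area_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 10.0)


class TestEstimateTransition:
    def test_identity_when_no_change(self, checkerboard):
        _, tm = estimate_transition(checkerboard, checkerboard, 5)
        assert np.allclose(tm.p, np.eye(2))

    def test_four_pixel_hand_tally(self):
        t1 = cmap([[1, 1], [2, 2]])
        t2 = cmap([[1, 2], [2, 2]])
        counts, tm = estimate_transition(t1, t2, 5)
        assert counts.n.tolist() == [[1, 1], [0, 2]]
        assert tm.p.tolist() == [[0.5, 0.5], [0.0, 1.0]]

    def test_rows_sum_to_one_on_random_maps(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            t1 = cmap(rng.integers(1, 3, size=(20, 20)))
            t2 = cmap(rng.integers(1, 3, size=(20, 20)))
            _, tm = estimate_transition(t1, t2, 1)
            assert np.allclose(tm.p.sum(axis=1), 1.0, atol=1e-9)

    def test_absent_class_gets_identity_row(self):
        t1 = cmap([[1, 1], [1, 1]])
        t2 = cmap([[1, 2], [1, 1]])
        with pytest.warns(UserWarning, match="persistence"):
            _, tm = estimate_transition(t1, t2, 5)
        assert tm.p[1].tolist() == [0.0, 1.0]

    def test_disjoint_validity_raises(self):
        with pytest.raises(RasterError):
            estimate_transition(cmap([[1, 0]]), cmap([[0, 1]]), 5)


class TestProjection:
    def test_identity_matrix_is_fixed_point(self):
        v = ClassProportions(np.array([0.3, 0.7]), 100.0)
        tm = TransitionMatrix(np.eye(2), 5.0)
        for h in (5, 10, 7.5):
            assert np.allclose(project_markov(v, tm, h).v, v.v, atol=1e-12)

    def test_one_interval_hand_multiplication(self):
        v = ClassProportions(np.array([0.5, 0.5]), 1000.0)
        tm = TransitionMatrix(M_STICKY, 5.0)
        out = project_markov(v, tm, 5.0)
        assert np.allclose(out.v, [0.55, 0.45], atol=1e-12)

    def test_stationary_limit_two_thirds(self):
        tm = TransitionMatrix(M_STICKY, 5.0)
        assert np.allclose(stationary_distribution(tm), [2 / 3, 1 / 3],
                           atol=1e-12)
        v = ClassProportions(np.array([0.5, 0.5]), 1.0)
        far = project_markov(v, tm, 5.0 * 200)
        assert np.allclose(far.v, [2 / 3, 1 / 3], atol=1e-9)

    def test_four_intervals_equals_four_single_steps(self):
        tm = TransitionMatrix(M_STICKY, 5.0)
        v = ClassProportions(np.array([0.5, 0.5]), 1.0)
        stepwise = v
        for _ in range(4):
            stepwise = project_markov(stepwise, tm, 5.0)
        assert np.allclose(project_markov(v, tm, 20.0).v, stepwise.v,
                           atol=1e-12)

    def test_fractional_power_oracle_equivalence(self):
        tm = TransitionMatrix(M_STICKY, 7.0)
        v = ClassProportions(np.array([0.42, 0.58]), 1.0)
        # horizon == interval must reproduce M itself
        assert np.allclose(project_markov(v, tm, 7.0).v, v.v @ M_STICKY,
                           atol=1e-9)
        # horizon == 2x interval must reproduce M @ M
        assert np.allclose(project_markov(v, tm, 14.0).v,
                           v.v @ (M_STICKY @ M_STICKY), atol=1e-9)

    def test_fractional_horizon_conserves_mass(self):
        tm = TransitionMatrix(M_STICKY, 7.0)
        v = ClassProportions(np.array([0.042, 0.958]), 1_419_211.6)
        df = project_series(v, tm, [10.0, 30.0])
        for h, grp in df.groupby("horizon_years"):
            assert grp.proportion.sum() == pytest.approx(1.0, abs=1e-12)
            assert grp.area_ha.sum() == pytest.approx(v.total_area_ha,
                                                      abs=1e-6)

    def test_convergence_to_stationary_is_monotone(self):
        tm = TransitionMatrix(M_STICKY, 1.0)
        pi = stationary_distribution(tm)
        v = ClassProportions(np.array([0.05, 0.95]), 1.0)
        dists = []
        cur = v
        for _ in range(15):
            dists.append(np.linalg.norm(cur.v - pi))
            cur = project_markov(cur, tm, 1.0)
        assert all(a >= b - 1e-12 for a, b in zip(dists, dists[1:]))

    def test_nonpositive_horizon_rejected(self):
        tm = TransitionMatrix(M_STICKY, 5.0)
        v = ClassProportions(np.array([0.5, 0.5]), 1.0)
        with pytest.raises(ValueError):
            project_markov(v, tm, 0.0)


class TestTransitionRecovery:
    def test_recovers_generating_matrix_within_3_binomial_se(self):
        cfg = synthetic.LandscapeConfig(n_rows=128, n_cols=128, n_epochs=3,
                                        M=M_STICKY, seed=123)
        truth = synthetic.simulate_landscape_series(cfg)
        counts, tm = estimate_transition(truth.class_maps[0],
                                         truth.class_maps[1],
                                         cfg.interval_years)
        for i in range(2):
            n_i = counts.row_totals[i]
            for j in range(2):
                p = M_STICKY[i, j]
                se = np.sqrt(p * (1 - p) / n_i)
                assert abs(tm.p[i, j] - p) < 3 * se


class TestChiSquare:
    def test_identical_observed_expected(self):
        r = chi_square_validate([50, 50], [50, 50])
        assert r.statistic == 0.0 and not r.reject

    def test_critical_value_df1(self):
        r = chi_square_validate([1, 1], [1, 1], q=2, alpha=0.05)
        assert r.df == 1
        assert r.critical == pytest.approx(3.841, abs=5e-4)

    def test_hand_example_rejects(self):
        r = chi_square_validate([60, 40], [50, 50])
        assert r.statistic == pytest.approx(4.0)
        assert r.reject

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            chi_square_validate([1, 2], [0, 3])
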