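import numpy as np
import pytest

from gazedyn.rqa import (
    corm,
    default_threshold_px,
    determinism,
    recurrence_matrix,
    recurrence_rate,
    rqa,
    rqa_table,
    threshold_sweep,
)


def brute_force_rqa(positions, d, min_line=2):
    """Independent O(N^2) reference for all three measures (pure python)."""
    n = len(positions)
    r = [[False] * n for _ in range(n)]
    R = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = positions[i][0] - positions[j][0]
            dy = positions[i][1] - positions[j][1]
            if (dx * dx + dy * dy) ** 0.5 <= d:
                r[i][j] = True
                R += 1
    rec = 100.0 * R / (n * (n - 1) / 2)
    if R == 0:
        return rec, 0.0, 0.0
    # determinism: recurrent points on diagonal runs of length >= min_line
    on_lines = 0
    for off in range(1, n):
        run = 0
        for i in range(0, n - off):
            if r[i][i + off]:
                run += 1
            else:
                if run >= min_line:
                    on_lines += run
                run = 0
        if run >= min_line:
            on_lines += run
    det = 100.0 * on_lines / R
    total = sum(j - i for i in range(n) for j in range(i + 1, n) if r[i][j])
    c = 100.0 * total / ((n - 1) * R)
    return rec, det, c


def random_path(rng, n=None):
    n = n or int(rng.integers(3, 61))
    # cluster or scatter to vary recurrence density
    if rng.random() < 0.5:
        return rng.normal([960, 540], rng.uniform(20, 150), size=(n, 2))
    return rng.uniform([0, 0], [1920, 1080], size=(n, 2))


class TestClosedForms:
    def test_constant_scanpath_fully_recurrent(self):
        pts = np.tile([100.0, 100.0], (10, 1))
        assert rqa(pts, d=50.0).recurrence == 100.0

    def test_all_pairs_beyond_threshold(self):
        pts = np.array([[0, 0], [1000, 0], [0, 1000]], dtype=float)
        m = recurrence_matrix(pts, 50.0)
        assert m.R == 0 and recurrence_rate(m) == 0.0

    def test_three_coincident_fixations_give_three_pairs(self):
        m = recurrence_matrix(np.zeros((3, 2)), 10.0)
        assert m.R == 3

    def test_recurrence_formula_n5_r2(self):
        # two recurrent pairs out of ten -> 20%
        pts = np.array([[0, 0], [0, 0], [500, 0], [1000, 0], [1000, 0]], dtype=float)
        m = recurrence_matrix(pts, 10.0)
        assert m.R == 2 and recurrence_rate(m) == pytest.approx(20.0)

    def test_constant_n4_determinism_hand_enumeration(self):
        # full upper triangle: offsets 1,2,3 have runs 3,2,1 -> 5 of 6 points
        m = recurrence_matrix(np.zeros((4, 2)), 1.0)
        assert determinism(m) == pytest.approx(500.0 / 6.0)

    def test_isolated_recurrent_point_zero_determinism(self):
        pts = np.array([[0, 0], [500, 500], [1, 1], [900, 100]], dtype=float)
        m = recurrence_matrix(pts, 10.0)
        assert m.R == 1 and determinism(m) == 0.0

    def test_corm_extreme_pair_first_to_last(self):
        n = 8
        pts = np.full((n, 2), 1e6)
        pts[0] = [0, 0]
        pts[-1] = [0, 0]
        pts[1:-1] = np.linspace([5000, 0], [5000 + 600 * n, 0], n - 2)
        m = recurrence_matrix(pts, 10.0)
        assert m.R == 1 and corm(m) == pytest.approx(100.0)

    def test_corm_adjacent_pair_n10(self):
        pts = np.linspace([0, 0], [9000, 0], 10)
        pts[4] = pts[5] = [4500, 0]
        m = recurrence_matrix(pts, 10.0)
        assert m.R == 1 and corm(m) == pytest.approx(100.0 / 9.0)

    def test_corm_full_matrix_n3(self):
        m = recurrence_matrix(np.zeros((3, 2)), 1.0)
        assert corm(m) == pytest.approx(100.0 * 4.0 / 6.0)


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_paths(self, rng):
        for _ in range(200):
            pts = random_path(rng)
            d = float(rng.uniform(20, 300))
            meas = rqa(pts, d=d)
            rec, det, c = brute_force_rqa(pts, d)
            assert meas.recurrence == pytest.approx(rec, abs=1e-9)
            assert meas.determinism == pytest.approx(det, abs=1e-9)
            assert meas.corm == pytest.approx(c, abs=1e-9)

    def test_composition_identity(self, rng):
        pts = random_path(rng, 40)
        meas = rqa(pts, d=100.0, min_line=2)
        m = recurrence_matrix(pts, 100.0)
        assert meas.recurrence == recurrence_rate(m)
        assert meas.determinism == determinism(m, 2)
        assert meas.corm == corm(m)


class TestProperties:
    def test_recurrence_monotone_in_threshold(self, rng):
        pts = random_path(rng, 50)
        rates = [rqa(pts, d=d).recurrence for d in (20, 50, 100, 200, 400, 3000)]
        assert rates == sorted(rates)
        assert rates[-1] == 100.0

    def test_recurrence_permutation_invariant_but_structure_not(self, rng):
        det_changed = 0
        for _ in range(20):
            pts = random_path(rng, 40)
            perm = rng.permutation(len(pts))
            a = rqa(pts, d=104.0)
            b = rqa(pts[perm], d=104.0)
            assert a.recurrence == pytest.approx(b.recurrence)
            if abs(a.determinism - b.determinism) > 1e-9 or abs(a.corm - b.corm) > 1e-9:
                det_changed += 1
        assert det_changed > 0  # order matters for determinism / CORM

    def test_measures_within_bounds(self, rng):
        for _ in range(100):
            meas = rqa(random_path(rng), d=float(rng.uniform(10, 500)))
            assert 0.0 <= meas.recurrence <= 100.0
            assert 0.0 <= meas.determinism <= 100.0
            assert 0.0 <= meas.corm <= 100.0

    def test_degenerate_zero_recurrence_flagged(self):
        pts = np.array([[0, 0], [900, 0], [0, 900]], dtype=float)
        meas = rqa(pts, d=10.0)
        assert meas.degenerate and meas.determinism == 0.0 and meas.corm == 0.0

    def test_below_two_fixations_raises(self):
        with pytest.raises(ValueError):
            recurrence_matrix(np.array([[0.0, 0.0]]), 10.0)

    def test_nonpositive_threshold_raises(self):
        with pytest.raises(ValueError):
            recurrence_matrix(np.zeros((3, 2)), 0.0)

    def test_threshold_at_exact_distance_is_inclusive(self):
        pts = np.array([[0, 0], [100, 0]], dtype=float)
        assert recurrence_matrix(pts, 100.0).R == 1
        assert recurrence_matrix(pts, 99.999).R == 0


class TestTables:
    def test_default_threshold_is_two_degrees(self):
        assert default_threshold_px() == pytest.approx(103.5, abs=0.5)

    def test_rqa_table_one_row_per_trial(self, small_experiment):
        tab = rqa_table(small_experiment.fixations, d=104.0)
        n_trials = small_experiment.trials[["participant", "trial"]].drop_duplicates()
        assert len(tab) == len(n_trials)
        assert {"recurrence", "determinism", "corm", "N", "R"} <= set(tab.columns)

    def test_threshold_sweep_recurrence_monotone(self, small_experiment):
        fx = small_experiment.fixations
        one_trial = fx[(fx.participant == 0) & (fx.trial < 6)]
        sweep = threshold_sweep(one_trial, [50.0, 100.0, 200.0])
        wide = sweep.pivot_table(index=["participant", "trial"], columns="threshold_px", values="recurrence")
        assert (wide[100.0] >= wide[50.0]).all() and (wide[200.0] >= wide[100.0]).all()
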