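import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazedyn.preprocess import exclude_trials, filter_fixations, spread


def fix_frame(rows):
    return pd.DataFrame(rows, columns=["x_px", "y_px", "duration_ms"])


class TestFilterFixations:
    def test_off_screen_dropped(self):
        kept, rep = filter_fixations(fix_frame([(-5, 100, 300), (500, 500, 300)]))
        assert len(kept) == 1 and rep.reasons["off_screen"] == 1

    @pytest.mark.parametrize(
        "duration,expect_kept",
        [(99.0, False), (100.0, True), (5000.0, True), (5001.0, False)],
    )
    def test_duration_bounds_inclusive(self, duration, expect_kept):
        kept, _ = filter_fixations(fix_frame([(500, 500, duration)]))
        assert (len(kept) == 1) == expect_kept

    def test_proportion_kept(self):
        rows = [(500, 500, 300)] * 7 + [(-1, 0, 300), (10, 10, 50), (10, 10, 9000)]
        kept, rep = filter_fixations(fix_frame(rows))
        assert rep.proportion_kept == pytest.approx(0.7)
        assert rep.reasons == {"off_screen": 1, "too_short": 1, "too_long": 1}

    def test_first_failing_rule_wins(self):
        # off-screen AND too short: counted once, as off-screen
        kept, rep = filter_fixations(fix_frame([(-1, 0, 10)]))
        assert rep.reasons == {"off_screen": 1, "too_short": 0, "too_long": 0}

    def test_empty_input_is_not_an_error(self):
        kept, rep = filter_fixations(fix_frame([]))
        assert len(kept) == 0 and rep.n_input == 0 and rep.proportion_kept == 1.0

    def test_order_preserved(self):
        df = fix_frame([(10, 10, 200), (-1, 0, 300), (20, 20, 300)])
        kept, _ = filter_fixations(df)
        assert list(kept["x_px"]) == [10, 20]

    def test_idempotent(self, rng):
        df = fix_frame(
            np.column_stack(
                [
                    rng.uniform(-100, 2100, 200),
                    rng.uniform(-100, 1200, 200),
                    rng.uniform(0, 9000, 200),
                ]
            )
        )
        once, rep1 = filter_fixations(df)
        twice, rep2 = filter_fixations(once)
        pd.testing.assert_frame_equal(once, twice)
        assert rep2.n_kept == rep2.n_input

    def test_invalid_screen_raises(self):
        with pytest.raises(ValueError):
            filter_fixations(fix_frame([(1, 1, 200)]), screen=(0, 1080))


class TestSpread:
    def test_degenerate_cluster_has_zero_spread(self):
        res = spread(np.tile([300.0, 200.0], (5, 1)))
        assert res.spread == 0.0 and res.centroid == (300.0, 200.0)

    def test_square_corners_spread_equals_half_diagonal(self):
        pts = np.array([[0, 0], [0, 10], [10, 0], [10, 10]], dtype=float)
        assert spread(pts).spread == pytest.approx(np.hypot(5, 5))

    def test_matches_brute_force_median(self, rng):
        pts = rng.uniform(0, 1000, size=(7, 2))
        centroid = pts.mean(axis=0)
        dists = sorted(np.hypot(*(p - centroid)) for p in pts)
        assert spread(pts).spread == pytest.approx(dists[3])

    def test_even_count_averages_middle_distances(self):
        pts = np.array([[0, 0], [1, 0], [4, 0], [9, 0]], dtype=float)
        centroid = pts.mean(axis=0)
        dists = sorted(abs(p[0] - centroid[0]) for p in pts)
        assert spread(pts).spread == pytest.approx((dists[1] + dists[2]) / 2)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            spread(np.empty((0, 2)))

    @given(
        dx=st.floats(-500, 500),
        dy=st.floats(-500, 500),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_translation_invariant_and_scale_linear(self, dx, dy, scale):
        pts = np.array([[0, 0], [50, 10], [20, 80], [90, 40], [10, 10]], dtype=float)
        base = spread(pts).spread
        assert spread(pts + [dx, dy]).spread == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert spread(pts * scale).spread == pytest.approx(base * scale, rel=1e-9)


class TestExcludeTrials:
    def trials(self):
        return pd.DataFrame(
            {
                "segments": [1, 1, 2, 2, 3, 4],
                "correct": [True, True, True, False, True, False],
                "rating": [3, 2, 7, 7, 1, 2],
            }
        )

    def test_keeps_correct_and_rated_at_least_three(self):
        kept, rep = exclude_trials(self.trials())
        assert len(kept) == 2
        assert set(zip(kept["segments"], kept["rating"])) == {(1, 3), (2, 7)}

    def test_report_counts(self):
        _, rep = exclude_trials(self.trials())
        assert rep.n_input == 6 and rep.n_kept == 2
        assert rep.n_wrong_answer == 2 and rep.n_low_rating == 2
        assert rep.proportion_excluded == pytest.approx(4 / 6)

    def test_per_segment_proportions(self):
        _, rep = exclude_trials(self.trials())
        by = rep.by_segment.set_index("segments")["proportion_excluded"]
        assert by[1] == pytest.approx(0.5) and by[3] == 1.0

    def test_exclusion_ignores_scanpath_columns(self):
        t = self.trials().assign(recurrence=np.linspace(0, 100, 6))
        kept_a, _ = exclude_trials(self.trials())
        kept_b, _ = exclude_trials(t)
        assert list(kept_a.index) == list(kept_b.index)

    def test_missing_fields_raise(self):
        with pytest.raises(KeyError):
            exclude_trials(pd.DataFrame({"correct": [True]}))
        bad = self.trials()
        bad.loc[2, "rating"] = np.nan
        with pytest.raises(ValueError, match="index 2"):
            exclude_trials(bad)
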