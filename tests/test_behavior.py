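import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadphys.behavior import (LabeledDataset, ObjectiveError, TrackingTrace,
                               assemble_dataset, correct_rating_outliers,
                               error_for_rating, select_rating_levels,
                               tracking_errors)
from dyadphys.errors import DataError, ProtocolError
from dyadphys.pipeline import FEATURE_COLUMNS


def make_trace(offsets):
    """Trace where ball-target offset at sample i is offsets[i] = (dx, dy)."""
    n = len(offsets)
    t = np.arange(n, dtype=float)
    tx = np.linspace(0, 100, n)
    ty = np.linspace(0, 50, n)
    dx = np.array([o[0] for o in offsets], dtype=float)
    dy = np.array([o[1] for o in offsets], dtype=float)
    return TrackingTrace(times=t, ball_x=tx + dx, ball_y=ty + dy,
                         target_x=tx, target_y=ty)


class TestTrackingErrors:
    def test_perfect_tracking(self):
        err = tracking_errors(make_trace([(0, 0)] * 5))
        assert (err.euclid_cum, err.x_cum, err.y_cum) == (0.0, 0.0, 0.0)

    def test_three_four_five(self):
        err = tracking_errors(make_trace([(0, 0), (3, 4), (0, 0)]))
        assert err.euclid_cum == pytest.approx(5.0)
        assert err.x_cum == pytest.approx(3.0)
        assert err.y_cum == pytest.approx(4.0)

    def test_axis_degenerate(self):
        err = tracking_errors(make_trace([(2, 0), (5, 0), (1, 0)]))
        assert err.euclid_cum == pytest.approx(err.x_cum)
        assert err.y_cum == 0.0

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            TrackingTrace(times=[0, 1], ball_x=[0, 1, 2], ball_y=[0, 1],
                          target_x=[0, 1], target_y=[0, 1])

    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_triangle_inequalities(self, offsets):
        err = tracking_errors(make_trace(offsets))
        assert err.euclid_cum <= err.x_cum + err.y_cum + 1e-9
        assert err.euclid_cum >= max(err.x_cum, err.y_cum) - 1e-9


class TestErrorForRating:
    ERR = ObjectiveError(euclid_cum=50.0, x_cum=30.0, y_cum=40.0)

    def test_r1_own_axis(self):
        assert error_for_rating("R1", "x", self.ERR) == 30.0
        assert error_for_rating("R1", "y", self.ERR) == 40.0

    def test_r2_partner_axis(self):
        assert error_for_rating("R2", "x", self.ERR) == 40.0
        assert error_for_rating("R2", "y", self.ERR) == 30.0

    def test_r3_euclidean(self):
        assert error_for_rating("R3", "x", self.ERR) == 50.0

    def test_individual_condition_protocol(self):
        with pytest.raises(ProtocolError):
            error_for_rating("R2", "x", self.ERR, condition="individual")
        with pytest.raises(ProtocolError):
            error_for_rating("R3", "x", self.ERR, condition="individual")

    def test_bad_kind(self):
        with pytest.raises(ProtocolError):
            error_for_rating("R4", "x", self.ERR)


class TestOutlierCorrection:
    def test_shared_median_no_correction(self):
        ratings = pd.Series([6, 6, 7, 6, 6, 7, 6, 6, 7])
        subjects = pd.Series([0, 0, 0, 1, 1, 1, 2, 2, 2])
        corrected, report = correct_rating_outliers(ratings, subjects)
        assert report == {}
        np.testing.assert_array_equal(corrected, ratings)

    def test_hand_quartile_case(self):
        # per-subject medians {6, 6, 7, 7, 6, 2}: quartiles on sorted
        # [2,6,6,6,7,7] give Q1=6, Q3=6.75, IQR=0.75 -> lower fence 4.875;
        # the subject with median 2 is flagged; others' median is 6 -> +4
        ratings, subjects = [], []
        for subj, med in enumerate([6, 6, 7, 7, 6, 2]):
            ratings += [med] * 5
            subjects += [subj] * 5
        corrected, report = correct_rating_outliers(pd.Series(ratings),
                                                    pd.Series(subjects))
        assert list(report) == [5]
        assert report[5] == pytest.approx(4.0)
        assert set(corrected[np.array(subjects) == 5]) == {6}

    def test_locality(self):
        ratings = pd.Series([6] * 5 + [7] * 5 + [6] * 5 + [1] * 5)
        subjects = pd.Series([0] * 5 + [1] * 5 + [2] * 5 + [3] * 5)
        corrected, report = correct_rating_outliers(ratings, subjects)
        assert 3 in report
        mask_others = (subjects != 3).values
        np.testing.assert_array_equal(corrected[mask_others],
                                      ratings[mask_others])

    def test_requires_three_subjects(self):
        with pytest.raises(DataError):
            correct_rating_outliers(pd.Series([5, 6]), pd.Series([0, 1]))


class TestLevelSelection:
    def test_identity_when_few_levels(self):
        keep, retained = select_rating_levels(pd.Series([5, 6, 7, 5, 6]))
        assert keep.all()
        assert retained == [5, 6, 7]

    def test_rarest_level_dropped(self):
        ratings = []
        for level, count in zip(range(3, 10), [1, 5, 9, 9, 8, 7, 6]):
            ratings += [level] * count
        keep, retained = select_rating_levels(pd.Series(ratings))
        assert retained == [4, 5, 6, 7, 8, 9]
        assert (~keep).sum() == 1  # the single level-3 trial

    def test_never_more_than_l_levels(self):
        rng = np.random.default_rng(0)
        ratings = pd.Series(rng.integers(1, 10, size=200))
        keep, retained = select_rating_levels(ratings)
        assert len(retained) == 6
        assert set(ratings[keep]) <= set(retained)

    def test_tie_break_prefers_level_near_median(self):
        # levels 1 and 6 tie in frequency; grand median sits near 5
        ratings = pd.Series([1] * 3 + [6] * 3 + [4] * 5 + [5] * 5
                            + [3] * 4 + [7] * 4 + [2] * 4)
        _, retained = select_rating_levels(ratings)
        assert 6 in retained and 1 not in retained


class TestAssembleDataset:
    def test_minmax_columns(self, medium_table):
        ds = assemble_dataset(medium_table, "R1", "collaborative",
                              "autonomic", list(FEATURE_COLUMNS))
        assert ds.X.min() >= 0.0 and ds.X.max() <= 1.0
        for j in range(ds.X.shape[1]):
            col = ds.X[:, j]
            if col.max() > col.min():
                assert col.min() == pytest.approx(0.0)
                assert col.max() == pytest.approx(1.0)

    def test_constant_column_maps_to_zero(self, medium_table):
        table = medium_table.copy()
        table["ecg_mean"] = 5.0
        ds = assemble_dataset(table, "R1", "collaborative", "autonomic",
                              list(FEATURE_COLUMNS))
        j = ds.feature_names.index("ecg_mean")
        np.testing.assert_array_equal(ds.X[:, j], 0.0)

    def test_objective_predictor_single_column(self, medium_table):
        ds = assemble_dataset(medium_table, "R3", "collaborative",
                              "objective", list(FEATURE_COLUMNS))
        assert ds.X.shape[1] == 1
        assert ds.feature_names == ["tracking_error_R3"]

    def test_r2_individual_rejected(self, medium_table):
        with pytest.raises(ProtocolError):
            assemble_dataset(medium_table, "R2", "individual", "autonomic",
                             list(FEATURE_COLUMNS))

    def test_at_most_six_levels(self, medium_table):
        ds = assemble_dataset(medium_table, "R1", "collaborative",
                              "autonomic", list(FEATURE_COLUMNS))
        assert len(set(ds.y)) <= 6
        assert sorted(set(ds.y.tolist())) == ds.retained_levels \
            or set(ds.y.tolist()) <= set(ds.retained_levels)

    def test_normalization_idempotent(self, medium_table):
        ds = assemble_dataset(medium_table, "R1", "collaborative",
                              "autonomic", list(FEATURE_COLUMNS))
        from dyadphys.behavior import _minmax
        again = _minmax(ds.X, ds.feature_names)
        np.testing.assert_allclose(again, ds.X, atol=1e-12)


class TestLabeledDataset:
    def test_shape_validation(self):
        with pytest.raises(DataError):
            LabeledDataset(X=np.zeros((3, 2)), y=np.zeros(4),
                           subject_ids=np.zeros(3), feature_names=["a", "b"])

    def test_subset_features(self):
        ds = LabeledDataset(X=np.arange(12.0).reshape(4, 3),
                            y=np.array([1, 1, 2, 2]),
                            subject_ids=np.zeros(4),
                            feature_names=["a", "b", "c"])
        sub = ds.subset_features(["c", "a"])
        assert sub.feature_names == ["c", "a"]
        np.testing.assert_array_equal(sub.X[:, 0], ds.X[:, 2])
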