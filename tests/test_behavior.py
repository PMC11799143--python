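"""Unit and property tests for the behavioral measurement pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from thinktime.behavior import (
    EmptyInputError,
    accuracy_by,
    annotate_trials,
    auc,
    cliffs_delta,
    filter_trials,
    group_compare,
    holm_adjust,
    irritation_scores,
    participant_accuracy,
    rt_category,
    rt_cdf,
    time_normalize,
    trajectory_auc,
)


def _trials(rows):
    return pd.DataFrame(
        rows, columns=["participant_id", "group", "proportion", "response", "rt_s"]
    )


def shoelace(x, y):
    """Signed polygon area oracle (counter-clockwise positive)."""
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


class TestAnnotateAndFilter:
    def test_correctness_and_difficulty_derivation(self):
        df = annotate_trials(
            _trials(
                [
                    ("p0", "0s", 0.55, "yes", 1.0),
                    ("p0", "0s", 0.55, "no", 1.0),
                    ("p0", "0s", 0.35, "no", 1.0),
                    ("p0", "0s", 0.45, "yes", 1.0),
                ]
            )
        )
        assert df["correct"].tolist() == [True, False, True, False]
        assert df["difficulty"].tolist() == ["difficult", "difficult", "easy",
                                             "difficult"]

    def test_missing_column_is_an_error(self):
        with pytest.raises(ValueError, match="rt_s"):
            annotate_trials(pd.DataFrame({"participant_id": [], "group": []}))

    def test_over_six_seconds_is_strict(self):
        df = _trials(
            [("p0", "0s", 0.55, "yes", r) for r in (5.9, 6.0, 6.1)]
        )
        kept, frac = filter_trials(df)
        assert kept["rt_s"].tolist() == [5.9, 6.0]
        assert frac == pytest.approx(1 / 3)

    def test_no_outliers_is_identity(self):
        df = _trials([("p0", "0s", 0.55, "yes", 1.0)] * 5)
        kept, frac = filter_trials(df)
        assert len(kept) == 5 and frac == 0.0

    def test_outlier_fraction_counted(self):
        rts = np.full(1000, 2.0)
        rts[:21] = 6.5
        df = _trials([("p0", "0s", 0.55, "yes", r) for r in rts])
        _, frac = filter_trials(df)
        assert frac == pytest.approx(0.021)

    def test_empty_table_signalled(self):
        with pytest.raises(EmptyInputError):
            filter_trials(_trials([]))


class TestTimeNormalize:
    def test_linear_segment(self):
        xn, yn = time_normalize([0.0, 1.0], [0.0, 100.0], [0.0, 200.0])
        assert len(xn) == len(yn) == 101
        np.testing.assert_allclose(xn, np.arange(101))
        np.testing.assert_allclose(yn, 2.0 * np.arange(101))

    def test_identity_on_already_normalized_input(self):
        t = np.linspace(0, 2, 101)
        x = np.sin(t)
        y = np.cos(t)
        xn, yn = time_normalize(t, x, y)
        np.testing.assert_allclose(xn, x, atol=1e-12)
        np.testing.assert_allclose(yn, y, atol=1e-12)

    def test_piecewise_interpolation_by_hand(self):
        xn, _ = time_normalize([0.0, 0.2, 1.0], [0.0, 10.0, 10.0], [0.0, 0.0, 0.0])
        assert xn[50] == pytest.approx(10.0)  # fraction 0.5 -> t = 0.5
        assert xn[10] == pytest.approx(5.0)  # fraction 0.1 -> t = 0.1

    def test_endpoints_preserved_exactly(self, rng):
        t = np.sort(rng.uniform(0, 3, 17))
        t[0], t[-1] = 0.0, 3.0
        x, y = rng.normal(size=17), rng.normal(size=17)
        xn, yn = time_normalize(t, x, y)
        assert (xn[0], yn[0]) == (x[0], y[0])
        assert (xn[-1], yn[-1]) == (x[-1], y[-1])

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            time_normalize([0.0], [1.0], [1.0])
        with pytest.raises(ValueError):
            time_normalize([1.0, 1.0], [0.0, 1.0], [0.0, 1.0])


class TestAUC:
    def test_straight_path_is_zero(self):
        x = np.linspace(0, 5, 50)
        assert auc(x, 2 * x) == pytest.approx(0.0, abs=1e-12)

    def test_unit_triangle(self):
        # start (0,0), end (2,0), apex (1,1): area 1, apex left of travel
        assert auc([0, 1, 2], [0, 1, 0]) == pytest.approx(1.0)

    def test_mirror_symmetric_excursions_cancel(self):
        s = np.linspace(0, 2 * np.pi, 101)
        assert auc(s, np.sin(s)) == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_shoelace_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 51))
            x = np.cumsum(rng.normal(size=n))
            y = np.cumsum(rng.normal(size=n))
            if np.hypot(x[-1] - x[0], y[-1] - y[0]) < 1e-6:
                continue
            area = shoelace(x, y)  # path + closing edge along the direct line
            assert auc(x, y) == pytest.approx(-area, rel=1e-6, abs=1e-9)

    @given(angle=st.floats(0, 2 * np.pi), tx=st.floats(-50, 50),
           ty=st.floats(-50, 50))
    @settings(derandomize=True, max_examples=50)
    def test_rigid_motion_invariance(self, angle, tx, ty):
        rng = np.random.default_rng(2)
        x = np.cumsum(rng.normal(size=20))
        y = np.cumsum(rng.normal(size=20))
        c, s = np.cos(angle), np.sin(angle)
        xr = c * x - s * y + tx
        yr = s * x + c * y + ty
        assert auc(xr, yr) == pytest.approx(auc(x, y), rel=1e-9, abs=1e-9)

    def test_quadratic_scaling(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 1.0, 0.0])
        assert auc(3 * x, 3 * y) == pytest.approx(9.0 * auc(x, y))

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(ValueError):
            auc([0, 1, 0], [0, 1, 0])

    def test_sign_flips_toward_reference(self):
        x, y = np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 0.0])
        up = trajectory_auc(x, y, toward=(1.0, 5.0))
        down = trajectory_auc(x, y, toward=(1.0, -5.0))
        assert up == pytest.approx(1.0)
        assert down == pytest.approx(-1.0)


class TestRTCategory:
    @pytest.mark.parametrize(
        "rt, label",
        [
            (0.8, "~1.0 s"),
            (1.0, "1.0–2.5 s"),
            (2.4999, "1.0–2.5 s"),
            (2.5, "2.5–4.0 s"),
            (4.0, "4.0 s ~"),
            (6.0, "4.0 s ~"),
        ],
    )
    def test_boundaries(self, rt, label):
        assert rt_category(rt) == label

    def test_unfiltered_rt_rejected(self):
        with pytest.raises(ValueError, match="filter"):
            rt_category(6.5)


class TestAccuracyTables:
    def test_cell_counting(self):
        df = annotate_trials(
            _trials(
                [("p0", "0s", 0.55, "yes", 1.0)] * 3
                + [("p0", "0s", 0.55, "no", 1.0)]
            )
        )
        table = accuracy_by(df, ["group", "difficulty"])
        assert table.loc[0, "n"] == 4
        assert table.loc[0, "accuracy"] == pytest.approx(0.75)

    def test_all_correct_cell(self):
        df = annotate_trials(_trials([("p0", "1s", 0.65, "yes", 2.0)] * 6))
        table = accuracy_by(df, ["group", "difficulty"])
        assert table["accuracy"].tolist() == [1.0]

    def test_per_participant_unit(self):
        df = annotate_trials(
            _trials(
                [("a", "0s", 0.55, "yes", 1.0)] * 2  # accuracy 1.0
                + [("b", "0s", 0.55, "no", 1.0)] * 2  # accuracy 0.0
            )
        )
        pp = participant_accuracy(df, ["group", "difficulty"])
        assert sorted(pp["accuracy"]) == [0.0, 1.0]


class TestRTCDF:
    def test_hand_counted_cdf(self):
        df = annotate_trials(
            _trials([("p0", "0s", 0.55, "yes", r) for r in (0.05, 0.15, 0.15)])
        )
        table = rt_cdf(df)
        stratum = table.set_index("bin_upper_s")["cumulative_prob"]
        assert stratum.loc[0.1] == pytest.approx(1 / 3)
        assert stratum.loc[0.2] == pytest.approx(1.0)

    def test_monotone_and_normalized(self, small_dataset):
        df, _ = filter_trials(annotate_trials(small_dataset.trials))
        table = rt_cdf(df)
        for _, g in table.groupby(["group", "difficulty", "correct"],
                                  observed=True):
            vals = g.sort_values("bin_upper_s")["cumulative_prob"].to_numpy()
            assert np.all(np.diff(vals) >= 0)
            assert vals[-1] == pytest.approx(1.0)


class TestIrritation:
    def test_maximum_of_blocks(self):
        ratings = pd.DataFrame(
            {
                "participant_id": ["p1"] * 9,
                "group": ["1s"] * 9,
                "block": range(1, 10),
                "rating": [10, 50, 20, 0, 0, 0, 0, 0, 30],
            }
        )
        out = irritation_scores(ratings)
        assert out.loc[0, "irritation"] == 50
        assert not out.loc[0, "excluded"]

    def test_all_zero_rater_flagged(self):
        ratings = pd.DataFrame(
            {
                "participant_id": ["p1"] * 9,
                "group": ["2.5s"] * 9,
                "block": range(1, 10),
                "rating": [0] * 9,
            }
        )
        assert irritation_scores(ratings).loc[0, "excluded"].item() is True

    def test_wrong_block_count_rejected(self):
        ratings = pd.DataFrame(
            {"participant_id": ["p1"] * 8, "group": ["1s"] * 8,
             "block": range(1, 9), "rating": [1] * 8}
        )
        with pytest.raises(ValueError, match="9"):
            irritation_scores(ratings)

    def test_out_of_scale_rating_rejected(self):
        ratings = pd.DataFrame(
            {"participant_id": ["p1"] * 9, "group": ["1s"] * 9,
             "block": range(1, 10), "rating": [101] + [0] * 8}
        )
        with pytest.raises(ValueError):
            irritation_scores(ratings)


class TestEffectSizes:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([3, 4, 5], [1, 2], 1.0),
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([1, 3], [2, 4], -0.5),
        ],
    )
    def test_cliffs_delta_enumerated(self, x, y, expected):
        assert cliffs_delta(x, y) == expected

    @given(
        x=st.lists(st.integers(-5, 5), min_size=1, max_size=8),
        y=st.lists(st.integers(-5, 5), min_size=1, max_size=8),
    )
    @settings(derandomize=True, max_examples=100)
    def test_cliffs_delta_antisymmetric_and_bounded(self, x, y):
        d = cliffs_delta(x, y)
        assert -1.0 <= d <= 1.0
        assert d == -cliffs_delta(y, x)

    def test_cliffs_delta_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cliffs_delta([], [1.0])

    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ([0.01, 0.04, 0.03], [0.03, 0.06, 0.06]),
            ([0.2], [0.2]),
            ([0.5, 0.9], [1.0, 1.0]),
        ],
    )
    def test_holm_hand_computed(self, pvals, expected):
        np.testing.assert_allclose(holm_adjust(pvals), expected)

    @given(
        pvals=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=10)
    )
    @settings(derandomize=True, max_examples=100)
    def test_holm_matches_statsmodels_and_dominates_input(self, pvals):
        ours = holm_adjust(pvals)
        theirs = multipletests(pvals, method="holm")[1]
        np.testing.assert_allclose(ours, theirs, rtol=1e-12, atol=1e-12)
        assert np.all(ours >= np.asarray(pvals) - 1e-15)

    def test_holm_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])


class TestGroupCompare:
    def test_identical_groups_give_zero_effect(self):
        res = group_compare({"a": [1, 2, 3], "b": [1, 2, 3]}, "anova+holm")
        assert res["F"] == pytest.approx(0.0, abs=1e-12)
        assert res["eta_squared"] == pytest.approx(0.0, abs=1e-12)

    def test_eta_squared_hand_dataset(self):
        # {1,2} vs {3,4}: SS_between = 4, SS_total = 5
        res = group_compare({"a": [1, 2], "b": [3, 4]}, "anova+holm")
        assert res["eta_squared"] == pytest.approx(0.8)

    def test_ranksum_with_separated_groups(self):
        res = group_compare({"hi": [4, 5, 6], "lo": [1, 2, 3]}, "ranksum")
        assert res["cliffs_delta"] == 1.0
        assert res["W"] == 9.0  # all 3x3 pairs won by the first group

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            group_compare({"a": [1.0], "b": [2.0, 3.0]})
        with pytest.raises(ValueError):
            group_compare({"a": [1, 2], "b": [3, 4]}, design="bootstrap")
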