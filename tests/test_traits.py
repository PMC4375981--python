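"""Unit and property tests for trait derivation formulas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gardenqg import traits
from gardenqg.exceptions import DegenerateInputError
from gardenqg.traits import (
    ScoringWindow,
    delta13c,
    derive_growth,
    derive_traits,
    injury_index,
    to_julian_day,
)


class TestDelta13C:
    @pytest.mark.parametrize(
        "r_sa, r_sd, expected",
        [
            (0.0112, 0.0112, 0.0),                      # sample equals standard
            (0.0112 * 1.1, 0.0112, 100.0),              # 10% enrichment = +100 per mil
            (0.0109, 0.0112, (0.0109 - 0.0112) / 0.0112 * 1000),  # hand arithmetic
        ],
    )
    def test_known_values(self, r_sa, r_sd, expected):
        assert delta13c(r_sa, r_sd) == pytest.approx(expected, abs=1e-10)

    def test_hand_value_is_depleted(self):
        # 0.0109 vs 0.0112 is about -26.8 per mil, a typical C3 plant value
        assert delta13c(0.0109, 0.0112) == pytest.approx(-26.7857142857, abs=1e-9)

    def test_invalid_standard(self):
        with pytest.raises(DegenerateInputError):
            delta13c(0.011, 0.0)

    @given(
        r_sd=st.floats(1e-4, 1.0),
        ratio=st.floats(0.5, 2.0),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, r_sd, ratio, scale):
        """delta13C depends only on the ratio of sample to standard."""
        base = delta13c(ratio * r_sd, r_sd)
        scaled = delta13c(scale * ratio * r_sd, scale * r_sd)
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestInjuryIndex:
    def test_no_injury_when_rt_equals_r0(self):
        assert injury_index(10.0, 100.0, 10.0, 100.0) == pytest.approx(0.0)

    def test_complete_injury_when_rt_is_one(self):
        for r0 in (0.05, 0.2, 0.5):
            assert injury_index(100.0, 100.0, r0 * 80, 80.0) == pytest.approx(100.0)

    def test_hand_arithmetic(self):
        # R_t = 0.55, R_0 = 0.10 -> 100 * 0.45 / 0.90 = 50
        assert injury_index(55.0, 100.0, 10.0, 100.0) == pytest.approx(50.0)

    def test_negative_values_not_clamped(self):
        assert injury_index(5.0, 100.0, 10.0, 100.0) < 0.0

    def test_degenerate_control(self):
        with pytest.raises(DegenerateInputError):
            injury_index(50.0, 100.0, 100.0, 100.0)

    @given(
        lt=st.lists(st.floats(1.0, 99.0), min_size=2, max_size=6, unique=True),
        r0=st.floats(0.01, 0.8),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_frozen_leakage(self, lt, r0):
        """More leakage from the frozen sample means more injury."""
        vals = [injury_index(x, 100.0, r0 * 50, 50.0) for x in sorted(lt)]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestGrowthTraits:
    def test_volume_index_formula(self):
        out = derive_growth(
            H=5.0, D=2.0, CD_ns=3.0, CD_ew=5.0, I_high=4.0, I_low=1.0,
            NB=10, NSyll=0, diameter_unit="cm",
        )
        assert out["VI"].iloc[0] == pytest.approx(20.0)       # D^2 * H
        assert out["CD"].iloc[0] == pytest.approx(4.0)
        assert out["RCD"].iloc[0] == pytest.approx(0.6)
        assert out["NSyll_log"].iloc[0] == pytest.approx(0.0)  # log(0+1)

    def test_branchless_span(self):
        out = derive_growth(
            H=5.0, D=2.0, CD_ns=3.0, CD_ew=3.0, I_high=2.0, I_low=2.0,
            NB=1, NSyll=1,
        )
        assert out["RCD"].iloc[0] == 0.0

    def test_branch_density(self):
        out = derive_growth(
            H=300.0, D=20.0, CD_ns=100.0, CD_ew=100.0, I_high=200.0, I_low=20.0,
            NB=30, NSyll=4,
        )
        assert out["RNB"].iloc[0] == pytest.approx(0.1)

    def test_diameter_unit_harmonization(self):
        mm = derive_growth(H=100.0, D=20.0, CD_ns=1, CD_ew=1, I_high=1, I_low=1,
                           NB=1, NSyll=1, diameter_unit="mm")
        cm = derive_growth(H=100.0, D=2.0, CD_ns=1, CD_ew=1, I_high=1, I_low=1,
                           NB=1, NSyll=1, diameter_unit="cm")
        assert mm["VI"].iloc[0] == pytest.approx(cm["VI"].iloc[0])

    def test_crown_diameter_order_invariant(self):
        a = derive_growth(H=5, D=2, CD_ns=3, CD_ew=7, I_high=4, I_low=1, NB=1, NSyll=1)
        b = derive_growth(H=5, D=2, CD_ns=7, CD_ew=3, I_high=4, I_low=1, NB=1, NSyll=1)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_height_rejected(self):
        with pytest.raises(DegenerateInputError):
            derive_growth(H=0.0, D=2, CD_ns=1, CD_ew=1, I_high=1, I_low=1,
                          NB=1, NSyll=1)


class TestJulianDay:
    def test_january_first(self):
        import datetime

        assert to_julian_day(datetime.date(2012, 1, 1)) == 1

    def test_left_censoring_one_week_before_first_visit(self):
        # already flushed at the first visit on day 92 -> recorded day 85
        win = ScoringWindow(first=92, last=120)
        assert to_julian_day(92, win, censored="left") == 85

    def test_right_censoring_one_week_after_last_visit(self):
        win = ScoringWindow(first=240, last=270)
        assert to_julian_day(270, win, censored="right") == 277

    def test_out_of_window_days_mapped_by_same_rule(self):
        win = ScoringWindow(first=92, last=120)
        assert to_julian_day(90, win) == 85
        assert to_julian_day(125, win) == 127
        assert to_julian_day(100, win) == 100


def test_derive_traits_full_table():
    """End-to-end derivation keeps design keys and produces the 12 traits."""
    raw = pd.DataFrame(
        {
            "block": ["B1", "B1"],
            "population": ["p1", "p1"],
            "genotype": ["g1", "g2"],
            "H": [300.0, 250.0],
            "D": [25.0, 20.0],
            "CD_ns": [110.0, 100.0],
            "CD_ew": [130.0, 90.0],
            "I_high": [250.0, 200.0],
            "I_low": [30.0, 20.0],
            "NB": [30, 25],
            "NSyll": [5, 0],
            "R_sa": [0.0109, 0.0110],
            "R_sd": [0.0112, 0.0112],
            "L_t": [55.0, 40.0],
            "L_k": [100.0, 100.0],
            "L_0": [10.0, 10.0],
            "L_d": [100.0, 100.0],
            "BF_date": [100, 105],
            "BS_date": [250, 260],
        }
    )
    out = derive_traits(raw)
    assert list(out.columns) == traits.DESIGN_COLUMNS + traits.TRAIT_NAMES
    assert out["I20"].iloc[0] == pytest.approx(50.0)
    assert out["VI"].iloc[0] == pytest.approx(2.5**2 * 300.0)
    assert out["BF"].tolist() == [100, 105]


def test_derive_traits_replicate_injury_segments_averaged():
    raw = pd.DataFrame(
        {
            "block": ["B1"], "population": ["p1"], "genotype": ["g1"],
            "H": [300.0], "D": [25.0], "CD_ns": [110.0], "CD_ew": [130.0],
            "I_high": [250.0], "I_low": [30.0], "NB": [30], "NSyll": [5],
            "R_sa": [0.0109], "R_sd": [0.0112],
            "L_t_1": [55.0], "L_k_1": [100.0], "L_0_1": [10.0], "L_d_1": [100.0],
            "L_t_2": [28.0], "L_k_2": [100.0], "L_0_2": [10.0], "L_d_2": [100.0],
            "L_t_3": [46.0], "L_k_3": [100.0], "L_0_3": [10.0], "L_d_3": [100.0],
            "BF_date": [100], "BS_date": [250],
        }
    )
    out = derive_traits(raw)
    expected = np.mean([50.0, 20.0, 40.0])
    assert out["I20"].iloc[0] == pytest.approx(expected)
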