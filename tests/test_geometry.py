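"""Unit and property tests for the spherical-pouch geometric model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from aadapt import (
    DomainError,
    IlealSegment,
    InputError,
    PlausibilityWarning,
    capacity,
    capacity_curve,
    expected_opened_width,
    length_curve,
    length_saving,
    percent_capacity_gain,
    plate_geometry,
    pressure_from_tension,
    required_length,
    required_width,
    wall_tension,
)

lengths = st.floats(min_value=0.01, max_value=100.0, allow_nan=False)
widths = st.floats(min_value=0.01, max_value=6.0, allow_nan=False)


class TestCapacity:
    @pytest.mark.parametrize(
        ("L", "w", "volume_ml"),
        [
            (40.0, 2.0, 190),  # narrow ileum, standard 40 cm harvest
            (40.0, 3.0, 350),  # 1 cm wider: nearly double the capacity
            (40.0, 2.2, 220),  # matches the bench-measured 220 ml pouch
        ],
    )
    def test_reported_capacities(self, L, w, volume_ml):
        assert round(capacity(length_cm=L, width_cm=w).volume_ml) == volume_ml

    def test_derived_capacity_full_precision(self):
        # closed form sqrt(2 (wL)^3 / (9 pi)) at wL = 88
        expected = math.sqrt(2 * 88.0**3 / (9 * math.pi))
        assert capacity(length_cm=40, width_cm=2.2).volume_ml == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(219.55, abs=0.01)

    def test_vanishing_segment_gives_vanishing_volume(self):
        assert capacity(length_cm=1e-9, width_cm=2.5).volume_ml < 1e-10

    @given(L=lengths, w=widths)
    @settings(max_examples=200, deadline=None)
    def test_sphere_identities(self, L, w):
        """Surface 2wL equals 4*pi*r^2 and V equals (4/3)*pi*r^3."""
        p = capacity(length_cm=L, width_cm=w)
        assert p.surface_area_cm2 == pytest.approx(2 * w * L, rel=1e-9)
        assert p.surface_area_cm2 == pytest.approx(
            4 * math.pi * p.radius_cm**2, rel=1e-9
        )
        assert p.volume_ml == pytest.approx(
            (4 / 3) * math.pi * p.radius_cm**3, rel=1e-9
        )

    @given(L=lengths, w=widths, k=st.floats(min_value=0.1, max_value=5))
    @settings(max_examples=200, deadline=None)
    def test_volume_scales_as_three_halves_power_of_length(self, L, w, k):
        v1 = capacity(length_cm=L, width_cm=w).volume_ml
        vk = capacity(length_cm=k * L, width_cm=w).volume_ml
        assert vk == pytest.approx(k**1.5 * v1, rel=1e-9)

    @given(L=lengths, w=widths, swap=st.floats(min_value=0.2, max_value=5))
    @settings(max_examples=200, deadline=None)
    def test_volume_depends_only_on_width_length_product(self, L, w, swap):
        v1 = capacity(length_cm=L, width_cm=w).volume_ml
        v2 = capacity(length_cm=L * swap, width_cm=w / swap).volume_ml
        assert v1 == pytest.approx(v2, rel=1e-9)

    def test_volume_strictly_increasing_in_each_dimension(self):
        grid = np.linspace(0.5, 6, 25)
        vols_w = [capacity(length_cm=40, width_cm=w).volume_ml for w in grid]
        vols_l = [capacity(length_cm=L, width_cm=2.5).volume_ml for L in grid * 10]
        assert np.all(np.diff(vols_w) > 0)
        assert np.all(np.diff(vols_l) > 0)

    @pytest.mark.parametrize("bad", [{"length_cm": 0, "width_cm": 2},
                                     {"length_cm": 40, "width_cm": -1},
                                     {"length_cm": math.nan, "width_cm": 2}])
    def test_domain_errors_name_the_field(self, bad):
        with pytest.raises(DomainError, match="length_cm|width_cm"):
            capacity(**bad)


class TestRequiredLength:
    @pytest.mark.parametrize(
        ("V", "w", "exact", "clinical"),
        [
            (350.0, 2.0, 60.0, 61),
            (350.0, 2.9, 41.4, 42),
            (350.0, 3.5, 34.3, 35),
        ],
    )
    def test_planning_examples(self, V, w, exact, clinical):
        plan = required_length(V, w)
        assert plan.exact_length_cm == pytest.approx(exact, abs=0.05)
        assert plan.clinical_length_cm == clinical

    def test_clinical_length_rounds_up_never_down(self):
        plan = required_length(350.0, 3.5)
        assert plan.clinical_length_cm == math.ceil(plan.exact_length_cm)
        assert plan.clinical_length_cm >= plan.exact_length_cm

    @given(L=lengths, w=widths)
    @settings(max_examples=300, deadline=None)
    def test_round_trip_inverse_identity(self, L, w):
        """required_length o capacity is the identity on length."""
        V = capacity(length_cm=L, width_cm=w).volume_ml
        assert required_length(V, w).exact_length_cm == pytest.approx(L, rel=1e-9)

    def test_agrees_with_bisection_oracle(self):
        """Closed form matches a numeric root-finder inverting capacity."""
        rng = np.random.default_rng(20231108)
        for _ in range(1000):
            w = rng.uniform(0.5, 6.0)
            V = rng.uniform(50.0, 800.0)
            root = brentq(
                lambda L: capacity(length_cm=L, width_cm=w).volume_ml - V,
                1e-6,
                500.0,
                xtol=1e-10,
            )
            assert abs(required_length(V, w).exact_length_cm - root) < 1e-6

    def test_length_strictly_decreasing_in_width(self):
        grid = np.linspace(1.5, 4.5, 30)
        Ls = [required_length(350, w).exact_length_cm for w in grid]
        assert np.all(np.diff(Ls) < 0)

    def test_rejects_non_positive_inputs(self):
        with pytest.raises(DomainError):
            required_length(0, 2)
        with pytest.raises(DomainError):
            required_length(350, -2)


class TestRequiredWidth:
    @pytest.mark.parametrize(
        ("V", "L", "w"), [(350.0, 40.0, 3.0), (190.0, 40.0, 2.0)]
    )
    def test_width_for_reported_pairs(self, V, L, w):
        assert required_width(V, L) == pytest.approx(w, abs=0.01)

    @given(L=lengths, w=widths)
    @settings(max_examples=200, deadline=None)
    def test_inverse_identity(self, L, w):
        V = capacity(length_cm=L, width_cm=w).volume_ml
        assert required_width(V, L) == pytest.approx(w, rel=1e-9)


class TestSensitivity:
    def test_one_cm_gain_from_two_cm_width(self):
        # (3/2)^(3/2) - 1 = 83.7%; commonly quoted rounded to 85%
        assert percent_capacity_gain(2.0, 1.0) == pytest.approx(83.7, abs=0.05)

    @pytest.mark.parametrize(
        ("w", "d", "pct"), [(2.0, 0.0, 0.0), (1.0, 3.0, 700.0)]
    )
    def test_closed_form_cases(self, w, d, pct):
        assert percent_capacity_gain(w, d) == pytest.approx(pct, abs=1e-9)

    @given(w=widths, d=st.floats(min_value=-0.5, max_value=3), L=lengths)
    @settings(max_examples=200, deadline=None)
    def test_gain_is_independent_of_length(self, w, d, L):
        if w + d <= 0.01:
            return
        via_model = 100 * (
            capacity(length_cm=L, width_cm=w + d).volume_ml
            / capacity(length_cm=L, width_cm=w).volume_ml
            - 1
        )
        assert percent_capacity_gain(w, d) == pytest.approx(via_model, rel=1e-9)

    def test_gain_rejects_collapsed_width(self):
        with pytest.raises(DomainError):
            percent_capacity_gain(2.0, -2.0)

    def test_length_saving_headline_values(self):
        assert length_saving(350, 2.0, 3.0) == pytest.approx(20.0, abs=0.05)
        assert length_saving(350, 2.0, 3.5) == pytest.approx(25.7, abs=0.05)
        assert length_saving(350, 2.5, 2.5) == 0.0


class TestPlateAndOpenedWidth:
    @pytest.mark.parametrize(
        ("L", "w", "pw", "pl"), [(40.0, 2.5, 10.0, 20.0), (40.0, 3.0, 12.0, 20.0)]
    )
    def test_plate_dimensions(self, L, w, pw, pl):
        plate = plate_geometry(IlealSegment(length_cm=L, width_cm=w))
        assert plate.plate_width_cm == pytest.approx(pw)
        assert plate.plate_length_cm == pytest.approx(pl)

    @given(L=st.floats(min_value=11, max_value=80), w=st.floats(min_value=2, max_value=3.5))
    @settings(max_examples=100, deadline=None)
    def test_plate_conserves_the_ileal_surface(self, L, w):
        plate = plate_geometry(IlealSegment(length_cm=L, width_cm=w))
        assert plate.plate_width_cm * plate.plate_length_cm == pytest.approx(
            2 * w * L, rel=1e-9
        )
        assert plate.plate_width_cm == pytest.approx(4 * w, rel=1e-9)

    @pytest.mark.parametrize(
        ("w", "d", "expected"),
        [(2.8, 0.19, 5.79), (3.0, 0.0, 6.0), (2.0, 0.24, 4.24)],
    )
    def test_opened_width(self, w, d, expected):
        assert expected_opened_width(w, d) == pytest.approx(expected)

    def test_opened_width_rejects_negative_allowance(self):
        with pytest.raises(DomainError):
            expected_opened_width(2.5, -0.1)


class TestLaplace:
    def test_doubling_radius_halves_pressure_at_fixed_tension(self):
        T = wall_tension(40.0, 3.0)
        assert pressure_from_tension(T, 6.0) == pytest.approx(20.0)

    def test_zero_pressure_gives_zero_tension(self):
        assert wall_tension(0.0, 3.0) == 0.0

    @given(
        P=st.floats(min_value=0, max_value=200),
        r=st.floats(min_value=0.1, max_value=10),
    )
    @settings(max_examples=100, deadline=None)
    def test_tension_pressure_round_trip(self, P, r):
        assert pressure_from_tension(wall_tension(P, r), r) == pytest.approx(
            P, abs=1e-9
        )

    def test_rejects_degenerate_radius(self):
        with pytest.raises(DomainError):
            wall_tension(40.0, 0.0)


class TestCurves:
    def test_capacity_curve_reproduces_reported_pairs(self):
        frame = capacity_curve(40.0, [2.0, 3.0, 3.5])
        assert [round(v) for v in frame["volume_ml"]] == [190, 350, 441]
        assert frame["volume_ml"].is_monotonic_increasing

    def test_length_curve_reproduces_planning_table(self):
        frame = length_curve(350.0, [2.0, 2.9, 3.5])
        assert frame["exact_length_cm"].round(1).tolist() == [60.0, 41.4, 34.3]
        assert frame["clinical_length_cm"].tolist() == [61, 42, 35]
        assert frame["exact_length_cm"].is_monotonic_decreasing

    def test_single_point_grid_matches_direct_evaluation(self):
        frame = capacity_curve(40.0, [2.7])
        assert len(frame) == 1
        assert frame.loc[0, "volume_ml"] == capacity(
            length_cm=40, width_cm=2.7
        ).volume_ml

    @pytest.mark.parametrize("grid", [[], [3.0, 2.0], [2.0, 2.0], [-1.0, 2.0]])
    def test_bad_grids_are_input_errors(self, grid):
        with pytest.raises(InputError):
            capacity_curve(40.0, grid)
        with pytest.raises(InputError):
            length_curve(350.0, grid)


class TestSegmentPlausibility:
    def test_in_range_segment_is_silent_and_plausible(self, recwarn):
        seg = IlealSegment(length_cm=40, width_cm=2.43)
        assert seg.plausible
        assert not [w for w in recwarn if w.category is PlausibilityWarning]

    @pytest.mark.parametrize(
        ("L", "w"), [(40.0, 1.2), (40.0, 4.5), (95.0, 2.5), (5.0, 2.5)]
    )
    def test_out_of_range_measurement_warns_but_is_usable(self, L, w):
        with pytest.warns(PlausibilityWarning):
            seg = IlealSegment(length_cm=L, width_cm=w)
        assert not seg.plausible
        assert capacity(seg).volume_ml > 0

    def test_non_positive_measurement_is_an_error(self):
        with pytest.raises(DomainError, match="width_cm"):
            IlealSegment(length_cm=40, width_cm=0)
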