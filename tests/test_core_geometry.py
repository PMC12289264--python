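"""Geometry layer: conversion, cosine-rule apex angle, arc length."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dalksizer import (
    ClinicalRangeWarning,
    CorneaModel,
    DomainError,
    GeometryError,
    apex_angle_from_chord,
    arc_length,
    diopters_to_radius,
    dm_arc_length,
    solve_arc,
)


def half_angle_oracle(radius: float, chord: float) -> float:
    """Independent apex-angle form: α = 2·arcsin(chord / 2r)."""
    return 2.0 * math.asin(chord / (2.0 * radius))


class TestDioptersToRadius:
    @pytest.mark.parametrize(
        "k, expected",
        [(45.0, 7.5), (67.5, 5.0), (337.5, 1.0), (50.0, 6.75), (60.0, 5.625)],
    )
    def test_standard_keratometric_conversion(self, k, expected):
        assert diopters_to_radius(k) == pytest.approx(expected, rel=1e-12)

    def test_custom_kindex(self):
        assert diopters_to_radius(43.0, kindex=344.0) == pytest.approx(8.0)

    @pytest.mark.parametrize("k, kindex", [(0.0, 337.5), (-45.0, 337.5), (45.0, 0.0)])
    def test_nonpositive_inputs_rejected(self, k, kindex):
        with pytest.raises(DomainError):
            diopters_to_radius(k, kindex)


class TestApexAngle:
    def test_published_worked_example(self):
        # 45 D cornea (r = 7.5 mm), 6 mm trephine: cos α = 0.68
        alpha = apex_angle_from_chord(7.5, 6.0)
        assert math.cos(alpha) == pytest.approx(0.68, abs=1e-12)
        assert alpha == pytest.approx(0.8230, abs=5e-5)

    def test_semicircle_chord_equals_diameter(self):
        assert apex_angle_from_chord(3.0, 6.0) == pytest.approx(math.pi)

    def test_vanishing_chord_vanishing_angle(self):
        assert apex_angle_from_chord(7.5, 1e-9) == pytest.approx(0.0, abs=1e-9)

    def test_chord_wider_than_sphere_is_geometry_error(self):
        with pytest.raises(GeometryError):
            apex_angle_from_chord(3.0, 6.01)

    @pytest.mark.parametrize("radius, chord", [(0.0, 1.0), (7.5, 0.0), (7.5, -1.0)])
    def test_nonpositive_inputs_rejected(self, radius, chord):
        with pytest.raises(DomainError):
            apex_angle_from_chord(radius, chord)

    @settings(derandomize=True, max_examples=300)
    @given(
        radius=st.floats(0.5, 50.0),
        frac=st.floats(1e-6, 1.0 - 1e-9),
    )
    def test_cosine_rule_agrees_with_half_angle_form(self, radius, frac):
        chord = 2.0 * radius * frac
        assert apex_angle_from_chord(radius, chord) == pytest.approx(
            half_angle_oracle(radius, chord), abs=1e-10
        )


class TestArcLength:
    def test_radius_times_angle(self):
        assert arc_length(7.5, 0.8) == pytest.approx(6.0)

    def test_zero_angle(self):
        assert arc_length(4.0, 0.0) == 0.0

    def test_full_circumference(self):
        assert arc_length(1.0, 2.0 * math.pi) == pytest.approx(2.0 * math.pi)

    def test_out_of_range_angle_rejected(self):
        with pytest.raises(DomainError):
            arc_length(7.5, -0.1)
        with pytest.raises(DomainError):
            arc_length(7.5, 2.0 * math.pi + 0.1)


class TestDmArcLength:
    @pytest.mark.parametrize(
        "k, trephine, printed",
        [(45.0, 6.00, 6.17), (70.0, 8.00, 9.43), (60.0, 7.50, 8.21)],
    )
    def test_matches_published_cells_at_two_decimals(self, k, trephine, printed):
        arc = dm_arc_length(k, trephine)
        assert round(arc * 100) / 100 == pytest.approx(printed, abs=1e-9)

    def test_arc_exceeds_chord(self):
        for k in (45.0, 55.0, 70.0):
            for t in (6.0, 7.0, 8.0):
                assert dm_arc_length(k, t) > t

    @pytest.mark.usefixtures("ignore_range_warnings")
    def test_flat_cornea_limit_arc_converges_to_chord(self):
        # K -> 0 flattens the sphere; the arc degenerates to its chord
        assert abs(dm_arc_length(0.001, 7.0) - 7.0) < 1e-6

    def test_strictly_increasing_in_curvature_and_trephine(self):
        ks = np.arange(45.0, 71.0)
        ts = np.arange(6.00, 8.01, 0.25)
        grid = np.array([[dm_arc_length(k, t) for t in ts] for k in ks])
        assert (np.diff(grid, axis=0) > 0).all()  # steeper cornea, longer arc
        assert (np.diff(grid, axis=1) > 0).all()  # wider trephine, longer arc

    def test_warns_outside_tabulated_envelope(self):
        with pytest.warns(ClinicalRangeWarning):
            dm_arc_length(42.0, 7.0)
        with pytest.warns(ClinicalRangeWarning):
            dm_arc_length(55.0, 9.5)

    def test_silent_inside_envelope(self, recwarn):
        dm_arc_length(55.0, 7.0)
        assert not any(
            isinstance(w.message, ClinicalRangeWarning) for w in recwarn.list
        )

    def test_solve_arc_consistency(self):
        sol = solve_arc(45.0, 6.0)
        assert sol.arc_length == pytest.approx(
            diopters_to_radius(45.0) * sol.apex_angle, rel=1e-12
        )


class TestCorneaModel:
    def test_from_keratometry_consistent(self):
        m = CorneaModel.from_keratometry(45.0)
        assert m.radius == pytest.approx(7.5)
        assert m.radius * m.keratometry == pytest.approx(m.kindex)

    def test_inconsistent_radius_rejected(self):
        with pytest.raises(DomainError):
            CorneaModel(keratometry=45.0, radius=8.0, kindex=337.5)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            CorneaModel(keratometry=-45.0, radius=7.5)
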