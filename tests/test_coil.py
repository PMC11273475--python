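"""Helmholtz coil field against closed forms and a segment-sum oracle."""

import numpy as np
import pytest

from mihsim.coil import (
    CoilSpec,
    DriveCurrent,
    calibrate_separation,
    center_flux_density,
    field_map_3d,
    helmholtz_axis_profile,
    helmholtz_center_closed_form,
    loop_axial_field,
    loop_field_offaxis,
    uniformity_report,
)
from mihsim.constants import MU0

DRIVE = DriveCurrent(amplitude=8.0, frequency=1.0e5)
THIN = CoilSpec(n_radial=1, n_axial=1)  # all turns at the mean radius


def biot_savart_segments(radius, current, point, n=10_000):
    """Brute-force line integral around the loop (y–z plane, axis = x),
    independent of the elliptic-integral implementation."""
    phi = 2.0 * np.pi * (np.arange(n) + 0.5) / n
    src = np.column_stack([np.zeros(n), radius * np.cos(phi), radius * np.sin(phi)])
    dl = np.column_stack(
        [np.zeros(n), -radius * np.sin(phi), radius * np.cos(phi)]
    ) * (2.0 * np.pi / n)
    r = np.asarray(point, dtype=float) - src
    norm = np.linalg.norm(r, axis=1) ** 3
    return MU0 * current / (4.0 * np.pi) * np.sum(
        np.cross(dl, r) / norm[:, None], axis=0
    )


class TestSingleLoop:
    def test_on_axis_closed_form_at_center(self):
        # μ0 I / 2R for a single turn at the loop plane
        assert loop_axial_field(0.145, 8.0, 0.0) == pytest.approx(3.4666e-5, rel=1e-4)

    def test_far_field_decay(self):
        assert loop_axial_field(0.145, 8.0, 1e3) < 1e-12

    def test_on_axis_matches_segment_sum(self):
        b = loop_axial_field(0.145, 8.0, 0.0725)
        oracle = biot_savart_segments(0.145, 8.0, (0.0725, 0.0, 0.0))[0]
        assert b == pytest.approx(oracle, rel=1e-4)

    @pytest.mark.parametrize(
        "point",
        [
            (0.0, 0.05, 0.0),
            (0.03, 0.05, 0.02),
            (-0.06, -0.08, 0.04),
            (0.0725, 0.10, -0.03),
        ],
    )
    def test_offaxis_matches_segment_sum(self, point):
        b = loop_field_offaxis(0.145, 8.0, point)
        oracle = biot_savart_segments(0.145, 8.0, point)
        assert np.linalg.norm(b - oracle) < 1e-3 * np.linalg.norm(oracle)

    def test_on_axis_has_no_radial_component(self):
        b = loop_field_offaxis(0.145, 8.0, (0.03, 0.0, 0.0))
        assert b[1] == 0.0 and b[2] == 0.0

    def test_field_flips_with_current_reversal(self):
        p = (0.01, 0.04, -0.02)
        assert np.allclose(
            loop_field_offaxis(0.145, 8.0, p), -loop_field_offaxis(0.145, -8.0, p)
        )

    def test_wire_singularity_guard(self):
        with pytest.raises(ValueError):
            loop_field_offaxis(0.145, 8.0, (0.0, 0.145, 0.0))
        capped = loop_field_offaxis(0.145, 8.0, (0.0, 0.145, 0.0), cap=True)
        assert np.all(np.isfinite(capped))


class TestHelmholtzPair:
    def test_thin_coil_center_matches_closed_form(self):
        b = center_flux_density(THIN, DRIVE)
        assert b == pytest.approx(helmholtz_center_closed_form(180, 8.0, 0.145), rel=1e-12)
        assert b * 1e3 == pytest.approx(8.930, abs=5e-3)

    def test_axis_profile_mirror_symmetry(self):
        xs = np.linspace(-0.06, 0.06, 25)
        b = np.asarray(helmholtz_axis_profile(CoilSpec(), DRIVE, xs).B)
        assert np.allclose(b, b[::-1], rtol=1e-12)

    def test_pair_is_superposition_of_single_coils(self):
        pts = np.array([[0.0, 0.0, 0.0], [0.01, 0.02, -0.01], [0.03, 0.0, 0.04]])
        coil = CoilSpec(n_radial=2, n_axial=3, turns=180)
        full = field_map_3d(coil, DRIVE, pts).B
        radii, x_loops, w = coil.loop_positions()
        half = len(radii) // 2
        partial = np.zeros_like(full)
        for r, xl in zip(radii, x_loops):
            shifted = pts.copy()
            shifted[:, 0] -= xl
            partial += w * np.array(
                [loop_field_offaxis(r, DRIVE.amplitude, p) for p in shifted]
            )
        assert np.allclose(full, partial, rtol=1e-12)

    def test_linear_scaling_in_current_and_turns(self):
        b1 = center_flux_density(CoilSpec(), DriveCurrent(amplitude=8.0))
        b2 = center_flux_density(CoilSpec(), DriveCurrent(amplitude=16.0))
        assert b2 == pytest.approx(2.0 * b1, rel=1e-12)
        b3 = center_flux_density(CoilSpec(turns=360), DriveCurrent(amplitude=8.0))
        assert b3 == pytest.approx(2.0 * b1, rel=1e-12)

    def test_helmholtz_quartic_flatness_at_center(self):
        # d²B/dx² vanishes for the ideal thin pair at separation = radius:
        # the central second difference shrinks as h² and is orders of
        # magnitude below that of a detuned (non-Helmholtz) separation
        def second_diff(coil, h):
            b = np.asarray(helmholtz_axis_profile(coil, DRIVE, [-h, 0.0, h]).B)
            return (b[0] - 2 * b[1] + b[2]) / h**2

        s1, s2 = second_diff(THIN, 2e-3), second_diff(THIN, 1e-3)
        assert abs(s2) < 0.3 * abs(s1)  # -> 0 as h -> 0 (ratio ~1/4)
        from dataclasses import replace

        detuned = replace(THIN, separation=0.145 * 1.3)
        assert abs(s2) < 1e-3 * abs(second_diff(detuned, 1e-3))

    def test_default_layout_reproduces_working_field_within_5pc(self):
        b = center_flux_density(CoilSpec(), DRIVE) * 1e3
        assert abs(b - 8.5621) / 8.5621 < 0.05

    def test_separation_calibration_roundtrip(self):
        cal = calibrate_separation(CoilSpec(), DRIVE, 8.5621e-3)
        assert center_flux_density(cal, DRIVE) == pytest.approx(8.5621e-3, rel=1e-10)
        assert 0.10 < cal.separation < 0.25  # stays a physical Helmholtz-like gap

    def test_h_is_b_over_mu0(self):
        fm = helmholtz_axis_profile(CoilSpec(), DRIVE, np.linspace(-0.02, 0.02, 5))
        assert np.allclose(fm.H, np.asarray(fm.B) / MU0)


class TestUniformity:
    def test_uniform_map_has_zero_ripple(self):
        from mihsim.coil import FieldMap

        pts = np.zeros((5, 3))
        pts[:, 0] = np.linspace(-1, 1, 5)
        fm = FieldMap(points=pts, B=np.full(5, 2.0))
        assert uniformity_report(fm)["ripple"] == 0.0

    def test_center_region_ripple_below_1pc(self):
        xs = np.linspace(-0.0145, 0.0145, 31)  # |x| <= R/10
        fm = helmholtz_axis_profile(THIN, DRIVE, xs)
        assert uniformity_report(fm)["ripple"] < 0.01

    def test_region_errors(self):
        fm = helmholtz_axis_profile(THIN, DRIVE, np.linspace(-0.01, 0.01, 5))
        with pytest.raises(ValueError):
            uniformity_report(fm, region=np.zeros(5, dtype=bool))
        with pytest.raises(ValueError):
            uniformity_report(fm, region=np.ones(9, dtype=bool))
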