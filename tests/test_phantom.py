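"""Analytic tube flow: profiles, flux conservation, xenon front transport."""

import math

import numpy as np
import pytest
from scipy.special import erfc

from xepcv.gases import XENON, InvalidGeometryError, InvalidPhysicsError
from xepcv.phantom import (
    AnalyticFlowField,
    TubePhantom,
    advect_concentration,
    poiseuille_velocity,
    sample_field,
    solve_concentration,
    womersley_velocity,
)


def disc_flux(u_of_r, R, n=4001):
    """Quadrature oracle: ∫ u(r)·2πr dr over the cross-section."""
    r = np.linspace(0.0, R, n)
    return np.trapezoid(u_of_r(r) * 2 * np.pi * r, r)


class TestPoiseuille:
    def test_no_slip(self):
        assert poiseuille_velocity(7.5e-3, 7.5e-3, 1e-4) == 0.0

    def test_centerline_hand_value(self):
        # 2Q/(πR²) = 2·3.1e-4/(π·7.5e-3²) ≈ 3.51 m/s
        assert poiseuille_velocity(0.0, 7.5e-3, 3.1e-4) == pytest.approx(3.51, abs=0.005)

    def test_half_maximum_radius(self):
        R = 7.5e-3
        u0 = poiseuille_velocity(0.0, R, 1e-4)
        assert poiseuille_velocity(R / math.sqrt(2), R, 1e-4) == pytest.approx(u0 / 2)

    def test_outside_wall_zero(self):
        assert poiseuille_velocity(1.0, 7.5e-3, 1e-4) == 0.0

    def test_invalid_radius(self):
        with pytest.raises(InvalidGeometryError):
            poiseuille_velocity(0.0, -1.0, 1e-4)

    def test_flux_equals_q(self):
        Q, R = 8e-5, 7.5e-3
        flux = disc_flux(lambda r: poiseuille_velocity(r, R, Q), R)
        assert flux == pytest.approx(Q, rel=1e-6)


class TestWomersleyProfile:
    R = 7.5e-3
    Q = 8e-5

    def test_no_slip_all_times(self):
        for t in (0.0, 0.3, 1.1, 2.9):
            assert womersley_velocity(self.R, t, self.R, 0.42, self.Q, XENON) == 0.0

    def test_low_alpha_matches_poiseuille(self):
        """At α = 0.01 the oscillatory profile is quasi-steady Poiseuille."""
        nu = XENON.kinematic_viscosity
        omega = (0.01 / self.R) ** 2 * nu  # sets α exactly to 0.01
        r = np.linspace(0.0, self.R, 500)
        t = 0.4
        u = womersley_velocity(r, t, self.R, omega, self.Q, XENON)
        u_ref = poiseuille_velocity(r, self.R, self.Q * math.cos(omega * t))
        assert np.linalg.norm(u - u_ref) / np.linalg.norm(u_ref) < 1e-3

    @pytest.mark.parametrize("t", [0.0, 0.7, 1.9, 4.4])
    def test_flux_amplitude(self, t):
        """Cross-section flux equals Q·cos(ωt) (quadrature oracle)."""
        omega = 0.42
        flux = disc_flux(
            lambda r: womersley_velocity(r, t, self.R, omega, self.Q, XENON), self.R
        )
        assert flux == pytest.approx(self.Q * math.cos(omega * t), abs=1e-3 * self.Q)

    def test_steady_requested_with_guidance(self):
        with pytest.raises(InvalidPhysicsError, match="poiseuille"):
            womersley_velocity(0.0, 0.0, self.R, 0.0, self.Q, XENON)

    def test_high_alpha_profile_flattens(self):
        """At large α the core profile is flatter than the parabola."""
        omega = 10.0  # α ≈ 11.9 for xenon at R = 7.5 mm
        r = np.linspace(0.0, self.R, 200)
        u = womersley_velocity(r, 0.0, self.R, omega, self.Q, XENON)
        u_par = poiseuille_velocity(r, self.R, self.Q)
        core = r < 0.3 * self.R
        assert np.ptp(u[core]) < 0.2 * np.ptp(u_par[core])


class TestFlowField:
    def test_outside_lumen_zero(self, steady_field):
        v = sample_field(steady_field, np.array([[0.05, 0.0, 0.0]]), 1.0)
        assert np.all(v == 0.0)

    def test_centerline_matches_poiseuille(self, steady_field, tube):
        v = sample_field(steady_field, np.array([[0.0, 0.0, 0.0]]), 1.0)
        u_expect = poiseuille_velocity(0.0, tube.radius, 8e-5)
        assert v[0, 2] == pytest.approx(tube.inhale_sign * u_expect)
        assert v[0, 0] == v[0, 1] == 0.0

    def test_randomized_positions_match_formula(self, steady_field, tube):
        rng = np.random.default_rng(3)
        pts = rng.uniform([-0.01, -0.01, -0.09], [0.01, 0.01, 0.09], size=(200, 3))
        v = sample_field(steady_field, pts, 0.5)
        r = np.hypot(pts[:, 0], pts[:, 1])
        expect = np.where(
            r <= tube.radius,
            tube.inhale_sign * poiseuille_velocity(r, tube.radius, 8e-5),
            0.0,
        )
        np.testing.assert_allclose(v[:, 2], expect, atol=1e-14)

    def test_time_outside_trace_raises(self, breath_trace, tube):
        field = AnalyticFlowField(tube, breath_trace, mode="steady")
        with pytest.raises(ValueError, match="support"):
            field.velocity(np.zeros((1, 3)), 1e4)

    def test_velocity_series_consistent_with_single_time(self, breath_trace, tube):
        field = AnalyticFlowField(tube, breath_trace, mode="oscillatory", n_harmonics=4)
        rng = np.random.default_rng(11)
        pts = rng.uniform([-0.008, -0.008, -0.05], [0.008, 0.008, 0.05], size=(50, 3))
        times = np.array([0.5, 2.0, 7.7])
        series = field.velocity_series(pts, times)
        for i, t in enumerate(times):
            np.testing.assert_allclose(series[i], field.velocity(pts, float(t)), atol=1e-13)

    def test_oscillatory_flux_matches_reconstruction(self, breath_trace, tube):
        """Numerically integrated axial flux equals the Fourier-reconstructed Q(t)."""
        field = AnalyticFlowField(tube, breath_trace, mode="oscillatory", n_harmonics=5)
        t = 5.0
        r = np.linspace(0.0, tube.radius, 3001)
        pts = np.zeros((len(r), 3))
        pts[:, 0] = r * 0.999999  # stay strictly inside the wall
        v = field.velocity(pts, t)
        flux = np.trapezoid(tube.inhale_sign * v[:, 2] * 2 * np.pi * r, r)
        assert flux == pytest.approx(field.flow_rate(t), rel=5e-3)

    def test_constriction_continuity_speedup(self):
        """Halving the radius quadruples the local mean axial speed."""
        ph = TubePhantom(constriction_depth=0.5, constriction_width=0.03)
        field = AnalyticFlowField(ph, 8e-5, mode="steady")

        def mean_speed_at(z):
            r_loc = ph.radius_at(ph.axial_distance(np.array([z]))).item()
            r = np.linspace(0, r_loc * 0.999999, 2001)
            pts = np.zeros((len(r), 3))
            pts[:, 0] = r
            pts[:, 2] = z
            u = -field.velocity(pts, 0.0)[:, 2]
            return np.trapezoid(u * 2 * np.pi * r, r) / (math.pi * r_loc**2)

        z_apex = ph.z_high - ph.constriction_center  # radius halved here
        ratio = mean_speed_at(z_apex) / mean_speed_at(ph.z_high - 0.005)
        assert ratio == pytest.approx(4.0, rel=0.01)

    def test_constriction_flux_conserved(self):
        """Integrated flux equals Q at every axial station (within quasi-1D tolerance)."""
        ph = TubePhantom(constriction_depth=0.5, constriction_width=0.03)
        field = AnalyticFlowField(ph, 8e-5, mode="steady")
        for s in (0.02, ph.constriction_center, 0.17):
            z = ph.z_high - s
            r_loc = ph.radius_at(np.array([s])).item()
            r = np.linspace(0, r_loc * 0.999999, 3001)
            pts = np.zeros((len(r), 3))
            pts[:, 0] = r
            pts[:, 2] = z
            u = -field.velocity(pts, 0.0)[:, 2]
            flux = np.trapezoid(u * 2 * np.pi * r, r)
            assert flux == pytest.approx(8e-5, rel=5e-3)


class TestConcentration:
    def test_plug_flow_sharp_front(self, tube):
        """Zero diffusion: front sits at x = (Q/A)·t, sharp to a few cells."""
        Q, t = 8e-5, 0.2
        cf = solve_concentration(tube, Q, diffusion_cm2s=0.0, t_end=t, n_cells=400)
        v = Q / tube.area_at(np.array([0.0])).item()
        x_front = v * t
        ds = cf.s_grid[1] - cf.s_grid[0]
        c = cf.at(cf.s_grid, t)
        # front midpoint lands on x = v·t to within one cell
        x_half = cf.s_grid[np.argmin(np.abs(c - 0.5))]
        assert abs(x_half - x_front) < ds
        # transition confined to a narrow numerical band (< 10% of distance travelled)
        assert np.all(c[cf.s_grid < x_front - 16 * ds] > 0.99)
        assert np.all(c[cf.s_grid > x_front + 16 * ds] < 0.01)

    def test_erfc_front_oracle(self, tube):
        """Constant Q and D: front matches the closed-form erfc solution."""
        Q, t, D_cm = 1.767e-5, 1.5, 0.14
        cf = solve_concentration(tube, Q, diffusion_cm2s=D_cm, t_end=t, n_cells=800)
        v = Q / tube.area_at(np.array([0.0])).item()
        analytic = 0.5 * erfc((cf.s_grid - v * t) / (2 * math.sqrt(D_cm * 1e-4 * t)))
        assert np.max(np.abs(cf.at(cf.s_grid, t) - analytic)) < 0.01

    def test_conservation(self, tube):
        """Xenon in tube + cumulative outflow equals cumulative inlet influx."""
        cf = solve_concentration(tube, 8e-5, diffusion_cm2s=0.14, t_end=1.0, n_cells=300)
        content = cf.tube_content(len(cf.t_grid) - 1)
        assert content + cf.outflux[-1] == pytest.approx(cf.influx[-1], rel=1e-12)

    def test_bounded(self, breath_trace, tube):
        """Concentration stays in [0, 1] under a trace with exhalation."""
        cf = solve_concentration(
            tube, breath_trace, diffusion_cm2s=0.14, t_end=18.0, n_cells=200
        )
        assert cf.conc.min() >= 0.0 and cf.conc.max() <= 1.0

    def test_negative_diffusion_rejected(self, tube):
        with pytest.raises(InvalidPhysicsError):
            solve_concentration(tube, 8e-5, diffusion_cm2s=-0.1, t_end=1.0)

    def test_time_outside_trace_rejected(self, breath_trace, tube):
        with pytest.raises(ValueError, match="support"):
            advect_concentration(tube, breath_trace, 0.14, t=1e4)


def test_phantom_invariants():
    with pytest.raises(InvalidGeometryError):
        TubePhantom(radius=-1.0)
    with pytest.raises(InvalidGeometryError):
        TubePhantom(constriction_depth=1.5)
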