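"""Analytic airway flow phantom: the ground-truth velocity field.

A straight tube (optionally with a smooth axisymmetric constriction) carries
oscillatory laminar axial flow driven by a measured breath trace, standing in
for a full flow simulation of a subject-specific airway.  Two profile modes
are provided:

* ``steady`` — quasi-steady Poiseuille: parabolic profile with instantaneous
  flux Q(t).  Valid when the Womersley number α ≪ 1.
* ``oscillatory`` — the breath trace is decomposed into a mean plus a few
  Fourier harmonics and each harmonic contributes a classical Womersley
  (Bessel-function) profile whose cross-section flux equals that harmonic.
  Captures the flattened, phase-lagged profiles that appear when α > 1, as in
  the airway experiments (α ≈ 4.9).

A 1-D advection-diffusion model tracks the ¹²⁹Xe molar fraction as the
inhaled gas front displaces the air initially filling the airway; the local
MR signal is proportional to this fraction.

Geometry convention: tube axis along foot-head (FH); with the default
``inhale_sign = -1`` a positive (inhalation) flow rate produces velocity in
the head→foot direction (negative v_FH), i.e. gas travelling down toward the
lungs, and the xenon front enters at the head end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import special

from .breath import BreathTrace
from .gases import GasProperties, InvalidGeometryError, InvalidPhysicsError, XENON

__all__ = [
    "TubePhantom",
    "AnalyticFlowField",
    "ConcentrationField",
    "poiseuille_velocity",
    "womersley_velocity",
    "advect_concentration",
    "solve_concentration",
    "sample_field",
]


@dataclass(frozen=True)
class TubePhantom:
    """A straight airway-like tube along the foot-head axis.

    Parameters
    ----------
    radius : float
        Base lumen radius, m.
    length : float
        Tube length, m.
    center_rl, center_ap : float
        World coordinates of the tube axis, m.
    z_low : float
        World FH coordinate of the lower (foot-side) end, m.
    gas : GasProperties
        Gas whose viscosity/density set the oscillatory profile shape.
    constriction_depth : float
        Fractional radius reduction at the constriction apex (0 = none,
        0.5 = radius halved).
    constriction_center : float
        Axial position of the constriction apex, m from the inlet end.
    constriction_width : float
        Gaussian 1σ width of the constriction, m.
    inhale_sign : float
        FH direction of travel of inhaled gas (+1 foot→head, −1 head→foot).
    """

    radius: float = 7.5e-3
    length: float = 0.20
    center_rl: float = 0.0
    center_ap: float = 0.0
    z_low: float = -0.10
    gas: GasProperties = field(default=XENON)
    constriction_depth: float = 0.0
    constriction_center: float = 0.10
    constriction_width: float = 0.02
    inhale_sign: float = -1.0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0:
            raise InvalidGeometryError("radius and length must be positive")
        if not 0.0 <= self.constriction_depth < 1.0:
            raise InvalidGeometryError("constriction depth must be in [0, 1)")
        if self.inhale_sign not in (-1.0, 1.0):
            raise ValueError("inhale_sign must be +1 or -1")

    # -- axial coordinate ---------------------------------------------------
    @property
    def z_high(self) -> float:
        return self.z_low + self.length

    def axial_distance(self, z: np.ndarray) -> np.ndarray:
        """Distance from the inlet end along the flow direction, m."""
        z = np.asarray(z, dtype=float)
        if self.inhale_sign < 0:  # inlet at the head end
            return self.z_high - z
        return z - self.z_low

    def radius_at(self, s: np.ndarray) -> np.ndarray:
        """Lumen radius at axial distance ``s`` from the inlet, m."""
        s = np.asarray(s, dtype=float)
        if self.constriction_depth == 0.0:
            return np.full_like(s, self.radius)
        dip = self.constriction_depth * np.exp(
            -0.5 * ((s - self.constriction_center) / self.constriction_width) ** 2
        )
        return self.radius * (1.0 - dip)

    def area_at(self, s: np.ndarray) -> np.ndarray:
        """Cross-sectional area at axial distance ``s``, m²."""
        return math.pi * self.radius_at(s) ** 2

    def contains(self, points_m: np.ndarray) -> np.ndarray:
        """Boolean lumen membership for (N,3) world points (m), RL/AP/FH order."""
        p = np.atleast_2d(points_m)
        r = np.hypot(p[:, 0] - self.center_rl, p[:, 1] - self.center_ap)
        z = p[:, 2]
        s = self.axial_distance(z)
        in_z = (z >= self.z_low) & (z <= self.z_high)
        return in_z & (r <= self.radius_at(np.clip(s, 0.0, self.length)))


def poiseuille_velocity(r: np.ndarray, R: float, Q: float) -> np.ndarray:
    """Steady parabolic profile u(r) = 2Q/(πR²)·(1 − r²/R²); zero outside the wall.

    ``r`` radial position (m), ``R`` tube radius (m), ``Q`` volumetric flow
    (m³·s⁻¹).  Satisfies no-slip at r = R and integrates to exactly Q over the
    cross-section.
    """
    if R <= 0:
        raise InvalidGeometryError("tube radius must be positive")
    r = np.asarray(r, dtype=float)
    u = 2.0 * Q / (math.pi * R**2) * (1.0 - (r / R) ** 2)
    return np.where(r <= R, u, 0.0)


def _womersley_profile(rho: np.ndarray, alpha: float) -> np.ndarray:
    """Complex radial shape ψ(ρ) of the oscillatory tube solution.

    ``rho`` = r/R in [0, 1]; ``alpha`` = R√(ω/ν) (radius-based Womersley
    number).  Normalized so that ∫₀¹ ψ·2ρ dρ = 1, i.e. the flux of
    Re{Q̂ ψ(r/R) e^{iωt}}/(πR²) equals Re{Q̂ e^{iωt}}.
    """
    lam = 1j**1.5 * alpha
    j0_lam = special.jv(0, lam)
    shape = 1.0 - special.jv(0, lam * rho) / j0_lam
    flux = 1.0 - 2.0 * special.jv(1, lam) / (lam * j0_lam)
    return shape / flux


def womersley_velocity(
    r: np.ndarray,
    t: float,
    R: float,
    omega: float,
    Q_amplitude: complex,
    gas: GasProperties,
) -> np.ndarray:
    """Oscillatory laminar axial velocity u(r, t), m·s⁻¹.

    The classical Bessel-function solution for flow in a rigid circular tube
    under a single-frequency drive, scaled so the cross-section flux is
    Re{Q_amplitude·e^{iωt}} (for real ``Q_amplitude``: Q(t) = Q·cos ωt).
    No-slip holds at r = R for all t.  As α = R√(ωρ/μ) → 0 the profile tends
    to quasi-steady Poiseuille at the instantaneous flow rate.
    """
    if omega <= 0:
        raise InvalidPhysicsError(
            "omega must be positive for the oscillatory solution; "
            "use poiseuille_velocity for steady flow"
        )
    if R <= 0:
        raise InvalidGeometryError("tube radius must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r > R * (1 + 1e-12)):
        raise ValueError("womersley_velocity expects r <= R")
    alpha = R * math.sqrt(omega / gas.kinematic_viscosity)
    if alpha < 1e-4:  # below double-precision resolution of the Bessel terms
        q_t = (Q_amplitude * np.exp(1j * omega * t)).real
        return poiseuille_velocity(r, R, q_t)
    psi = _womersley_profile(np.clip(r / R, 0.0, 1.0), alpha)
    u = (Q_amplitude * psi * np.exp(1j * omega * t)).real / (math.pi * R**2)
    return np.where(r <= R, u, 0.0)


def _fourier_components(
    trace: BreathTrace, n_harmonics: int
) -> tuple[float, float, np.ndarray, float]:
    """Decompose Q(t) (m³/s) into mean + complex harmonic amplitudes.

    Returns (t0, Q0, c_k for k=1..n, period); the reconstruction is
    Q(t) ≈ Q0 + Σ_k Re{c_k e^{i k ω₁ (t − t0)}} with ω₁ = 2π/period.
    """
    t0, t1 = trace.support
    period = t1 - t0
    q = np.asarray(trace.flow_m3s_at(trace.time))
    # uniform sampling -> rectangle-rule Fourier coefficients
    tau = trace.time - t0
    q0 = float(np.mean(q))
    ks = np.arange(1, n_harmonics + 1)
    phases = np.exp(-2j * math.pi * np.outer(ks, tau) / period)
    coeffs = 2.0 * (phases @ q) / len(q)
    return t0, q0, coeffs, period


class AnalyticFlowField:
    """Continuous space-time velocity field of a driven tube phantom.

    Parameters
    ----------
    phantom : TubePhantom
    drive : BreathTrace or float
        Measured flow trace (mL/s channel, interpolated) or a constant flow
        rate in m³·s⁻¹.
    mode : {"steady", "oscillatory"}
        Quasi-steady Poiseuille versus Fourier-superposed Womersley profiles.
    n_harmonics : int
        Number of Fourier harmonics retained in oscillatory mode.
    """

    def __init__(
        self,
        phantom: TubePhantom,
        drive: BreathTrace | float,
        mode: str = "steady",
        n_harmonics: int = 5,
    ) -> None:
        if mode not in ("steady", "oscillatory"):
            raise ValueError("mode must be 'steady' or 'oscillatory'")
        if mode == "oscillatory" and not isinstance(drive, BreathTrace):
            raise ValueError("oscillatory mode needs a BreathTrace drive")
        self.phantom = phantom
        self.drive = drive
        self.mode = mode
        self.n_harmonics = n_harmonics
        if mode == "oscillatory":
            self._t0, self._q0, self._ck, self._period = _fourier_components(
                drive, n_harmonics
            )

    @property
    def support(self) -> tuple[float, float]:
        if isinstance(self.drive, BreathTrace):
            return self.drive.support
        return (-math.inf, math.inf)

    def flow_rate(self, t: float) -> float:
        """Driving flow rate Q(t), m³·s⁻¹ (Fourier reconstruction in
        oscillatory mode — the flux the analytic profiles integrate to)."""
        if self.mode == "oscillatory":
            k = np.arange(1, self.n_harmonics + 1)
            osc = (self._ck * np.exp(2j * math.pi * k * (t - self._t0) / self._period)).real
            return float(self._q0 + osc.sum())
        if isinstance(self.drive, BreathTrace):
            return float(self.drive.flow_m3s_at(t))
        return float(self.drive)

    def _check_time(self, t: float) -> None:
        lo, hi = self.support
        if not (lo <= t <= hi):
            raise ValueError(f"time {t} outside drive support [{lo}, {hi}]")

    def velocity(self, points_m: np.ndarray, t: float) -> np.ndarray:
        """Velocity vectors (RL, AP, FH) in m·s⁻¹ at (N,3) world points (m).

        Points outside the lumen get the zero vector (no-slip wall and
        surrounding tissue).
        """
        self._check_time(t)
        p = np.atleast_2d(np.asarray(points_m, dtype=float))
        out = np.zeros_like(p)
        ph = self.phantom
        inside = ph.contains(p)
        if not inside.any():
            return out
        pin = p[inside]
        r = np.hypot(pin[:, 0] - ph.center_rl, pin[:, 1] - ph.center_ap)
        s = np.clip(ph.axial_distance(pin[:, 2]), 0.0, ph.length)
        R_loc = ph.radius_at(s)
        u = np.zeros(len(pin))
        if self.mode == "steady":
            q_t = self.flow_rate(t)
            u = 2.0 * q_t / (math.pi * R_loc**2) * (1.0 - (r / R_loc) ** 2)
        else:
            # mean component: Poiseuille; harmonics: Womersley, each with the
            # local radius (quasi-1D continuity through the constriction)
            u = 2.0 * self._q0 / (math.pi * R_loc**2) * (1.0 - (r / R_loc) ** 2)
            nu = ph.gas.kinematic_viscosity
            rho_rel = np.clip(r / R_loc, 0.0, 1.0)
            for k in range(1, self.n_harmonics + 1):
                w_k = 2.0 * math.pi * k / self._period
                alpha = R_loc * math.sqrt(w_k / nu)
                lam = 1j**1.5 * alpha
                j0_lam = special.jv(0, lam)
                shape = 1.0 - special.jv(0, lam * rho_rel) / j0_lam
                flux = 1.0 - 2.0 * special.jv(1, lam) / (lam * j0_lam)
                phase = np.exp(1j * w_k * (t - self._t0))
                u = u + (self._ck[k - 1] * (shape / flux) * phase).real / (
                    math.pi * R_loc**2
                )
        out[inside, 2] = ph.inhale_sign * u
        return out

    def velocity_series(
        self,
        points_m: np.ndarray,
        times: np.ndarray,
        out: np.ndarray | None = None,
    ) -> np.ndarray:
        """Velocity at fixed points for many times, shape (T, N, 3), m·s⁻¹.

        Equivalent to stacking :meth:`velocity` over ``times`` but factorizes
        the time-independent radial profiles, so the Bessel functions are
        evaluated once per point rather than once per (point, time).
        ``out`` may supply a preallocated (T, N, 3) buffer for reuse in tight
        loops.
        """
        times = np.asarray(times, dtype=float)
        for t in (times.min(), times.max()):
            self._check_time(float(t))
        p = np.atleast_2d(np.asarray(points_m, dtype=float))
        if out is None:
            out = np.zeros((len(times), len(p), 3))
        else:
            if out.shape != (len(times), len(p), 3):
                raise ValueError("out buffer has wrong shape")
            out[:] = 0.0
        ph = self.phantom
        inside = ph.contains(p)
        if not inside.any():
            return out
        pin = p[inside]
        r = np.hypot(pin[:, 0] - ph.center_rl, pin[:, 1] - ph.center_ap)
        s = np.clip(ph.axial_distance(pin[:, 2]), 0.0, ph.length)
        R_loc = ph.radius_at(s)
        base = 2.0 / (math.pi * R_loc**2) * (1.0 - (r / R_loc) ** 2)
        if self.mode == "steady":
            q_t = np.array([self.flow_rate(float(t)) for t in times])
            u = q_t[:, None] * base[None, :]
        else:
            u = np.tile(self._q0 * base, (len(times), 1))
            nu = ph.gas.kinematic_viscosity
            rho_rel = np.clip(r / R_loc, 0.0, 1.0)
            inv_area = 1.0 / (math.pi * R_loc**2)
            for k in range(1, self.n_harmonics + 1):
                w_k = 2.0 * math.pi * k / self._period
                alpha = R_loc * np.sqrt(w_k / nu)
                lam = 1j**1.5 * alpha
                j0_lam = special.jv(0, lam)
                shape = 1.0 - special.jv(0, lam * rho_rel) / j0_lam
                flux = 1.0 - 2.0 * special.jv(1, lam) / (lam * j0_lam)
                psi = self._ck[k - 1] * (shape / flux) * inv_area
                phases = np.exp(1j * w_k * (times - self._t0))
                u = u + (phases[:, None] * psi[None, :]).real
        out[:, inside, 2] = ph.inhale_sign * u
        return out


def sample_field(
    field: AnalyticFlowField, positions_m: np.ndarray, t: float
) -> np.ndarray:
    """Evaluate the analytic field at world positions (m); out-of-range times raise."""
    return field.velocity(positions_m, t)


@dataclass
class ConcentrationField:
    """Axial ¹²⁹Xe molar-fraction history c(s, t) on the phantom, values in [0, 1].

    ``s_grid`` are cell-centre axial distances from the inlet (m); ``t_grid``
    the stored times (s); ``conc`` has shape (len(t_grid), len(s_grid)).
    Cumulative inlet influx and end outflux of xenon volume (m³) are tracked
    for conservation checks.
    """

    phantom: TubePhantom
    s_grid: np.ndarray
    t_grid: np.ndarray
    conc: np.ndarray
    influx: np.ndarray
    outflux: np.ndarray

    def at(self, s: np.ndarray, t: float) -> np.ndarray:
        """Interpolated xenon fraction at axial distances ``s`` (m) and time ``t``."""
        ti = np.clip(np.searchsorted(self.t_grid, t), 1, len(self.t_grid) - 1)
        t_lo, t_hi = self.t_grid[ti - 1], self.t_grid[ti]
        w = 0.0 if t_hi == t_lo else (t - t_lo) / (t_hi - t_lo)
        w = min(max(w, 0.0), 1.0)
        c_lo = np.interp(s, self.s_grid, self.conc[ti - 1])
        c_hi = np.interp(s, self.s_grid, self.conc[ti])
        return np.clip((1.0 - w) * c_lo + w * c_hi, 0.0, 1.0)

    def at_world(self, points_m: np.ndarray, t: float) -> np.ndarray:
        """Xenon fraction at (N,3) world points (m)."""
        p = np.atleast_2d(points_m)
        s = np.clip(self.phantom.axial_distance(p[:, 2]), 0.0, self.phantom.length)
        return self.at(s, t)

    def tube_content(self, t_index: int) -> float:
        """Xenon volume inside the tube at stored time index, m³."""
        areas = self.phantom.area_at(self.s_grid)
        ds = self.s_grid[1] - self.s_grid[0]
        return float(np.sum(self.conc[t_index] * areas * ds))


class UniformConcentration:
    """Degenerate concentration field: lumen uniformly filled with xenon."""

    def __init__(self, value: float = 1.0) -> None:
        if not 0.0 <= value <= 1.0:
            raise ValueError("concentration must be in [0, 1]")
        self.value = value

    def at_world(self, points_m: np.ndarray, t: float) -> np.ndarray:
        p = np.atleast_2d(points_m)
        return np.full(len(p), self.value)


def solve_concentration(
    phantom: TubePhantom,
    drive: BreathTrace | float,
    diffusion_cm2s: float,
    t_end: float,
    t_start: float = 0.0,
    n_cells: int = 200,
    store_every: int = 20,
) -> ConcentrationField:
    """Finite-volume 1-D advection-diffusion of the inhaled xenon front.

    The tube starts filled with air (c = 0); all inflow at the inlet is pure
    xenon (c = 1).  Mean axial speed is Q(t)/A(s) by continuity; diffusion is
    the binary coefficient in cm²·s⁻¹.  Finite-volume scheme: second-order
    MUSCL advection with a minmod slope limiter (keeps the front sharp
    instead of smearing it numerically) plus explicit central diffusion,
    advanced with Heun (RK2) time stepping under a CFL-limited step; the flux
    form is conservative by construction.
    """
    if diffusion_cm2s < 0:
        raise InvalidPhysicsError("diffusion coefficient must be non-negative")
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    D = diffusion_cm2s * 1e-4  # m²/s
    ds = phantom.length / n_cells
    s = (np.arange(n_cells) + 0.5) * ds
    area_c = phantom.area_at(s)  # cell-centre areas
    area_f = phantom.area_at(np.arange(n_cells + 1) * ds)  # face areas
    vol = area_c * ds
    c = np.zeros(n_cells)

    def q_at(t: float) -> float:
        if isinstance(drive, BreathTrace):
            return float(drive.flow_m3s_at(t))
        return float(drive)

    def face_fluxes(c: np.ndarray, q: float) -> np.ndarray:
        """Advective + diffusive xenon volume fluxes at the n+1 faces, m³/s."""
        # minmod-limited slopes (per cell, in concentration units)
        dl = np.empty(n_cells)
        dr = np.empty(n_cells)
        dl[1:] = c[1:] - c[:-1]
        dl[0] = c[0] - (1.0 if q >= 0 else c[0])  # inlet ghost
        dr[:-1] = c[1:] - c[:-1]
        dr[-1] = 0.0  # zero-gradient outlet
        slope = np.where(dl * dr > 0, np.sign(dl) * np.minimum(np.abs(dl), np.abs(dr)), 0.0)
        flux = np.empty(n_cells + 1)
        if q >= 0:
            flux[0] = q * 1.0  # pure xenon enters
            flux[1:] = q * (c + 0.5 * slope)
        else:
            flux[-1] = q * c[-1]
            flux[:-1] = q * (c - 0.5 * slope)
        if D > 0:
            flux[1:-1] += -D * area_f[1:-1] * (c[1:] - c[:-1]) / ds
        return flux

    # stable step: advective CFL on the narrowest face + diffusive limit
    v_max = max(abs(q_at(tt)) for tt in np.linspace(t_start, t_end, 50)) / area_f.min()
    dt_adv = 0.4 * ds / v_max if v_max > 0 else math.inf
    dt_dif = 0.4 * ds**2 / D if D > 0 else math.inf
    dt = min(dt_adv, dt_dif, (t_end - t_start) / 10.0)
    n_steps = int(math.ceil((t_end - t_start) / dt))
    dt = (t_end - t_start) / n_steps

    times = [t_start]
    history = [c.copy()]
    influx = [0.0]
    outflux = [0.0]
    cum_in = 0.0
    cum_out = 0.0
    for step in range(n_steps):
        t = t_start + step * dt
        f1 = face_fluxes(c, q_at(t))
        c_pred = c + dt * (f1[:-1] - f1[1:]) / vol
        f2 = face_fluxes(np.clip(c_pred, 0.0, 1.0), q_at(t + dt))
        flux = 0.5 * (f1 + f2)
        c = c + dt * (flux[:-1] - flux[1:]) / vol
        c = np.clip(c, 0.0, 1.0)
        cum_in += flux[0] * dt
        cum_out += flux[-1] * dt
        if (step + 1) % store_every == 0 or step == n_steps - 1:
            times.append(t + dt)
            history.append(c.copy())
            influx.append(cum_in)
            outflux.append(cum_out)
    return ConcentrationField(
        phantom=phantom,
        s_grid=s,
        t_grid=np.array(times),
        conc=np.array(history),
        influx=np.array(influx),
        outflux=np.array(outflux),
    )


def advect_concentration(
    phantom: TubePhantom,
    drive: BreathTrace | float,
    diffusion_cm2s: float,
    t: float,
    **kwargs,
) -> ConcentrationField:
    """Concentration field advected from a fresh air-filled tube up to time ``t``."""
    if isinstance(drive, BreathTrace):
        lo, hi = drive.support
        if not (lo <= t <= hi):
            raise ValueError(f"time {t} outside trace support [{lo}, {hi}]")
        return solve_concentration(phantom, drive, diffusion_cm2s, t, t_start=lo, **kwargs)
    return solve_concentration(phantom, drive, diffusion_cm2s, t, **kwargs)
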