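"""Gas properties, dynamic similarity and kinetic-theory calculations.

Hyperpolarized ¹²⁹Xe is denser and more viscous than air, so an inhalation of
xenon is aerodynamically equivalent to a *faster, shorter* inhalation of air.
The translation between the two gases is done by matching the Reynolds number

    Re = ρ Q D / (μ A)

and the Womersley number

    α = D √(ω ρ / μ)

which yields a single scale factor (ρ_src/μ_src)·(μ_tgt/ρ_tgt) that converts
both volumetric flow rates and angular frequencies between gases.

The module also provides the Chapman-Enskog first-approximation binary
diffusion coefficient (used to model the mixing of inhaled xenon with resident
air) and the Kolmogorov dissipation length scale (used to judge whether a
simulation mesh resolves the finest flow structures).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "GasProperties",
    "FlowCondition",
    "XENON",
    "AIR",
    "reynolds_number",
    "equivalent_flow_rate",
    "womersley_number",
    "equivalent_angular_frequency",
    "equivalent_duration",
    "similarity_factor",
    "chapman_enskog_diffusion",
    "kolmogorov_length",
    "dissipation_estimate",
    "load_gas_table",
    "round_sig",
]


class InvalidGeometryError(ValueError):
    """Airway geometry (diameter / area) is non-physical."""


class InvalidPhysicsError(ValueError):
    """A physical parameter is outside its admissible range."""


@dataclass(frozen=True)
class GasProperties:
    """Bulk and molecular properties of a single gas species.

    Parameters
    ----------
    name : str
        Species label (e.g. ``"xenon-129"``).
    density : float
        Mass density ρ, kg·m⁻³.
    dynamic_viscosity : float
        Dynamic viscosity μ, Pa·s.
    molar_mass : float
        Molar mass, g·mol⁻¹.
    lj_sigma : float, optional
        Lennard-Jones collision diameter σ, Å (needed for diffusion only).
    lj_eps_over_k : float, optional
        Lennard-Jones well depth ε/k_B, K (needed for diffusion only).
    """

    name: str
    density: float
    dynamic_viscosity: float
    molar_mass: float
    lj_sigma: float | None = None
    lj_eps_over_k: float | None = None

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0 or self.molar_mass <= 0:
            raise InvalidPhysicsError(
                f"gas {self.name!r}: density, viscosity and molar mass must be positive"
            )
        for attr in ("lj_sigma", "lj_eps_over_k"):
            v = getattr(self, attr)
            if v is not None and v <= 0:
                raise InvalidPhysicsError(f"gas {self.name!r}: {attr} must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        """ν = μ/ρ, m²·s⁻¹."""
        return self.dynamic_viscosity / self.density


#: ¹²⁹Xe at body conditions.  Density and viscosity follow the values used for
#: dynamic-similarity scaling of the inhalation experiments; the molar mass is
#: that of the ¹²⁹Xe isotope (the inhaled gas is isotopically enriched, and the
#: density 5.761 kg·m⁻³ is itself consistent with M = 129 g·mol⁻¹).
XENON = GasProperties(
    name="xenon-129",
    density=5.761,
    dynamic_viscosity=2.28e-5,
    molar_mass=129.0,
    lj_sigma=4.047,
    lj_eps_over_k=231.0,
)

#: Dry air (treated as a single pseudo-species).
AIR = GasProperties(
    name="air",
    density=1.18,
    dynamic_viscosity=1.81e-5,
    molar_mass=28.96,
    lj_sigma=3.711,
    lj_eps_over_k=78.6,
)

_BUILTIN = {"xenon": XENON, "xenon-129": XENON, "xe": XENON, "air": AIR}


@dataclass(frozen=True)
class FlowCondition:
    """A volumetric flow through a conduit cross-section.

    flow_rate Q in m³·s⁻¹ (may be negative for exhalation), hydraulic diameter
    D in m, cross-sectional area A in m², angular frequency ω in rad·s⁻¹
    (0 for steady flow).
    """

    flow_rate: float
    hydraulic_diameter: float
    cross_section_area: float
    angular_frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.hydraulic_diameter <= 0 or self.cross_section_area <= 0:
            raise InvalidGeometryError("hydraulic diameter and area must be positive")
        if self.angular_frequency < 0:
            raise InvalidPhysicsError("angular frequency must be non-negative")


def reynolds_number(gas: GasProperties, cond: FlowCondition) -> float:
    """Reynolds number Re = ρ Q D / (μ A) for a flow condition."""
    return (
        gas.density
        * cond.flow_rate
        * cond.hydraulic_diameter
        / (gas.dynamic_viscosity * cond.cross_section_area)
    )


def similarity_factor(source: GasProperties, target: GasProperties) -> float:
    """Scale factor (ρ_src/μ_src)·(μ_tgt/ρ_tgt) carrying Q and ω between gases.

    Matching Reynolds numbers and matching Womersley numbers both reduce to
    multiplication by this single factor, so a flow-rate trace and its
    frequency content rescale consistently.  Identical gases give exactly 1.
    """
    if source == target:
        return 1.0
    return (source.density / source.dynamic_viscosity) * (
        target.dynamic_viscosity / target.density
    )


def equivalent_flow_rate(
    q_source: float, source: GasProperties, target: GasProperties
) -> float:
    """Flow rate of *target* gas dynamically similar to ``q_source`` of *source*.

    For ¹²⁹Xe → air with the package constants the factor is 3.88: an 80 mL/s
    xenon inhalation corresponds to a 310 mL/s air inhalation.
    """
    if not math.isfinite(q_source):
        raise InvalidPhysicsError("flow rate must be finite")
    return q_source * similarity_factor(source, target)


def womersley_number(gas: GasProperties, diameter: float, omega: float) -> float:
    """Womersley number α = D √(ω ρ / μ).

    ``diameter`` is the characteristic length (hydraulic diameter), m;
    ``omega`` the angular frequency of the flow oscillation, rad·s⁻¹.
    α > 1 indicates that transient inertial forces matter and the flow profile
    departs from quasi-steady Poiseuille.
    """
    if diameter <= 0:
        raise InvalidGeometryError("diameter must be positive")
    if omega < 0:
        raise InvalidPhysicsError("angular frequency must be non-negative")
    return diameter * math.sqrt(omega * gas.density / gas.dynamic_viscosity)


def equivalent_angular_frequency(
    omega_source: float, source: GasProperties, target: GasProperties
) -> float:
    """Angular frequency of *target* gas matching the Womersley number of *source*."""
    if omega_source < 0:
        raise InvalidPhysicsError("angular frequency must be non-negative")
    return omega_source * similarity_factor(source, target)


def equivalent_duration(
    duration_source: float, source: GasProperties, target: GasProperties
) -> float:
    """Breath duration of *target* gas equivalent to ``duration_source`` of *source*.

    Durations scale inversely to angular frequency: a 15 s xenon inhalation is
    equivalent to a ≈3.9 s inhalation of air.
    """
    if duration_source <= 0:
        raise InvalidPhysicsError("duration must be positive")
    omega = 2.0 * math.pi / duration_source
    return 2.0 * math.pi / equivalent_angular_frequency(omega, source, target)


# Neufeld et al. 8-parameter correlation for the reduced collision integral
# Ω_D(T*) of the Lennard-Jones (12-6) potential.
_NEUFELD = (1.06036, 0.15610, 0.19300, 0.47635, 1.03587, 1.52996, 1.76474, 3.89411)


def collision_integral(t_reduced: float) -> float:
    """Reduced diffusion collision integral Ω_D at reduced temperature T* = kT/ε."""
    if t_reduced <= 0:
        raise InvalidPhysicsError("reduced temperature must be positive")
    a, b, c, d, e, f, g, h = _NEUFELD
    return (
        a / t_reduced**b
        + c / math.exp(d * t_reduced)
        + e / math.exp(f * t_reduced)
        + g / math.exp(h * t_reduced)
    )


def chapman_enskog_diffusion(
    gas_a: GasProperties,
    gas_b: GasProperties,
    temperature: float = 310.0,
    pressure: float = 1.0,
) -> float:
    """Binary diffusion coefficient D_AB, cm²·s⁻¹, from kinetic theory.

    First Chapman-Enskog approximation

        D_AB = 1.8583e-3 · T^(3/2) · √(1/M_A + 1/M_B) / (p σ_AB² Ω_D)

    with σ_AB = (σ_A + σ_B)/2 (Å), ε_AB = √(ε_A ε_B), T in K, p in atm.
    Self-diffusion is the ``gas_a is gas_b`` case.  Defaults are body
    temperature (310 K) and atmospheric pressure.
    """
    if temperature <= 0 or pressure <= 0:
        raise InvalidPhysicsError("temperature and pressure must be positive")
    for g in (gas_a, gas_b):
        if g.lj_sigma is None or g.lj_eps_over_k is None:
            raise ValueError(
                f"gas {g.name!r} lacks Lennard-Jones parameters needed for diffusion"
            )
    sigma_ab = 0.5 * (gas_a.lj_sigma + gas_b.lj_sigma)
    eps_ab = math.sqrt(gas_a.lj_eps_over_k * gas_b.lj_eps_over_k)
    omega_d = collision_integral(temperature / eps_ab)
    return (
        1.8583e-3
        * temperature**1.5
        * math.sqrt(1.0 / gas_a.molar_mass + 1.0 / gas_b.molar_mass)
        / (pressure * sigma_ab**2 * omega_d)
    )


def kolmogorov_length(kinematic_viscosity: float, dissipation_rate: float) -> float:
    """Kolmogorov length η = (ν³/ε)^¼, m — smallest turbulent eddy scale."""
    if kinematic_viscosity <= 0 or dissipation_rate <= 0:
        raise InvalidPhysicsError("viscosity and dissipation rate must be positive")
    return (kinematic_viscosity**3 / dissipation_rate) ** 0.25


def dissipation_estimate(bulk_velocity: float, length_scale: float) -> float:
    """Heuristic dissipation rate ε ≈ U³/L, m²·s⁻³.

    Order-of-magnitude estimate only; use a measured or simulated dissipation
    field when available.
    """
    if length_scale <= 0:
        raise InvalidGeometryError("length scale must be positive")
    return abs(bulk_velocity) ** 3 / length_scale


def load_gas_table(path: str | Path) -> dict[str, GasProperties]:
    """Read a YAML/JSON gas-property table into ``GasProperties`` objects.

    Expected layout: a mapping of gas name to a mapping with keys
    ``density``, ``dynamic_viscosity``, ``molar_mass`` and optionally
    ``lj_sigma``, ``lj_eps_over_k``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    table = {}
    for name, entry in raw.items():
        table[name] = GasProperties(name=name, **entry)
    return table


def get_gas(name: str) -> GasProperties:
    """Look up a built-in gas by (case-insensitive) name."""
    try:
        return _BUILTIN[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown gas {name!r}; built-ins are {sorted(set(_BUILTIN))}"
        ) from None


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (for comparison at printed precision)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))
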