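"""Ideal-gas state relations for lumped gas volumes.

A gas node in the circuit is a fixed rigid volume whose mass and internal
energy respond to pressure and temperature through the ideal-gas law.  The
node balance equations integrate dp/dt (and dT/dt in the non-isothermal
mode) from the net mass and enthalpy fluxes, which requires the partial
derivatives of node mass and internal energy with respect to p and T; those
are provided here in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class DomainError(ValueError):
    """Physically inadmissible argument (non-positive pressure, volume, ...)."""


@dataclass(frozen=True)
class GasProperties:
    """Thermophysical constants of the working gas.

    Parameters
    ----------
    specific_gas_constant : float
        R, J/(kg·K).
    cv : float
        Specific heat at constant volume, J/(kg·K).
    dynamic_viscosity : float
        mu, Pa·s.
    reference_temperature : float
        Circuit gas temperature in isothermal operation, K.
    atmospheric_pressure : float
        Ambient absolute pressure, Pa; gauge pressures are relative to this.
    """

    specific_gas_constant: float = 287.05
    cv: float = 717.8
    dynamic_viscosity: float = 1.81e-5
    reference_temperature: float = 293.15
    atmospheric_pressure: float = 101325.0

    def __post_init__(self) -> None:
        for name in ("specific_gas_constant", "cv", "dynamic_viscosity",
                     "reference_temperature", "atmospheric_pressure"):
            if getattr(self, name) <= 0.0:
                raise DomainError(f"GasProperties.{name} must be positive")
        if self.cv >= self.specific_gas_constant * 10.0:
            raise DomainError("cv implausibly large relative to R")

    @property
    def cp(self) -> float:
        return self.cv + self.specific_gas_constant


AIR = GasProperties()


@dataclass(frozen=True)
class GasNodeState:
    """Thermodynamic state of one lumped gas volume (all SI)."""

    pressure_abs: float
    temperature: float
    volume: float
    mass: float = field(default=0.0)
    density: float = field(default=0.0)
    internal_energy: float = field(default=0.0)

    @classmethod
    def from_pTV(cls, pressure_abs: float, temperature: float, volume: float,
                 gas: GasProperties = AIR) -> "GasNodeState":
        mass = ideal_gas_mass(pressure_abs, temperature, volume, gas)
        density = mass / volume if volume > 0.0 else 0.0
        return cls(pressure_abs=pressure_abs, temperature=temperature,
                   volume=volume, mass=mass, density=density,
                   internal_energy=mass * gas.cv * temperature)

    def __post_init__(self) -> None:
        if self.pressure_abs <= 0.0:
            raise DomainError("absolute pressure must be positive")
        if self.volume > 0.0 and self.mass > 0.0:
            if abs(self.mass - self.density * self.volume) > 1e-9 * self.mass:
                raise DomainError("mass inconsistent with density × volume")


@dataclass(frozen=True)
class FlowState:
    """Signed flow through one connection; positive toward the patient."""

    mass_flow: float
    energy_flow: float
    upstream_pressure: float
    downstream_pressure: float
    upstream_density: float
    downstream_density: float


def _check_ptv(p_abs: float, temperature: float, volume: float) -> None:
    if p_abs <= 0.0 or temperature <= 0.0 or volume < 0.0:
        raise DomainError("require p_abs > 0, T > 0, V >= 0")


def ideal_gas_mass(p_abs: float, temperature: float, volume: float,
                   gas: GasProperties = AIR) -> float:
    """Gas mass in a rigid volume: M = p·V / (R·T), kg."""
    _check_ptv(p_abs, temperature, volume)
    return p_abs * volume / (gas.specific_gas_constant * temperature)


def mass_partials(p_abs: float, temperature: float, volume: float,
                  gas: GasProperties = AIR) -> tuple[float, float]:
    """(∂M/∂p, ∂M/∂T) of the node mass at fixed volume.

    ∂M/∂p = V/(R·T) [kg/Pa]; ∂M/∂T = −p·V/(R·T²) = −M/T [kg/K].
    """
    _check_ptv(p_abs, temperature, volume)
    r = gas.specific_gas_constant
    dm_dp = volume / (r * temperature)
    dm_dt = -p_abs * volume / (r * temperature * temperature)
    return dm_dp, dm_dt


def energy_partials(p_abs: float, temperature: float, volume: float,
                    gas: GasProperties = AIR) -> tuple[float, float]:
    """(∂U/∂p, ∂U/∂T) of the node internal energy at fixed volume.

    For an ideal gas U = M·cv·T = p·V·cv/R, so ∂U/∂p = V·cv/R and the
    temperature dependence cancels: ∂U/∂T = 0.
    """
    _check_ptv(p_abs, temperature, volume)
    return volume * gas.cv / gas.specific_gas_constant, 0.0
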