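"""Circuit components and their per-element physics.

Flow-resisting elements (tubing segments, reduced-lumen resistors,
endotracheal tubes) relate the signed mass flow through them to a pressure
loss; the lung is a Kelvin–Voigt element (elastic recoil V/C in parallel
with a viscous dashpot R_aw) whose flow responds to the applied airway
pressure.  Element interfaces are in clinical units where clinicians think
in them (mm lumen, ml/cmH₂O compliance); lengths and the loss functions are
SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import _kernels
from .gas import AIR, DomainError, GasProperties
from .units import PA_PER_CMH2O, resistance_to_si


@dataclass(frozen=True)
class PipeSegment:
    """Straight circular tubing segment.

    wall_heat_flow is the wall heat input Q_H used by the energy balance in
    non-isothermal mode (W, default 0 = adiabatic).
    """

    length: float
    inner_diameter: float
    wall_heat_flow: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0.0:
            raise DomainError("pipe length must be positive")
        if self.inner_diameter <= 0.0:
            raise DomainError("pipe diameter must be positive")

    @property
    def cross_section(self) -> float:
        return 0.25 * math.pi * self.inner_diameter ** 2

    @property
    def gas_volume(self) -> float:
        return self.cross_section * self.length


@dataclass(frozen=True)
class ResistorSpec:
    """Inline reduced-lumen flow resistor.

    lumen_diameter is the nominal label in mm (the narrowed bore); the
    graded taper of the physical part is condensed into a short throat of
    ``throat_length`` metres with contraction/expansion minor losses.
    """

    lumen_diameter: float  # mm
    throat_length: float = 0.02  # m
    discharge_coefficient: float = 0.9
    contraction_loss_coefficient: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 < self.lumen_diameter < 22.0:
            raise DomainError("resistor lumen diameter must be in (0, 22) mm")
        if self.throat_length <= 0.0:
            raise DomainError("throat length must be positive")
        if not 0.0 < self.discharge_coefficient <= 1.0:
            raise DomainError("discharge coefficient must be in (0, 1]")


@dataclass(frozen=True)
class EttSpec:
    """Endotracheal tube: dominates patient-side circuit resistance."""

    inner_diameter: float = 7.5  # mm
    length: float = 0.30  # m

    def __post_init__(self) -> None:
        if not 5.0 <= self.inner_diameter <= 10.0:
            raise DomainError("ETT inner diameter must be within [5, 10] mm")
        if self.length <= 0.0:
            raise DomainError("ETT length must be positive")


@dataclass(frozen=True)
class LungRC:
    """Single-compartment lung: compliance spring + airway-resistance dashpot.

    Airway pressure relates to volume above the relaxed state and flow by
    P_aw = V/C + R_aw · dV/dt (Kelvin–Voigt element).
    """

    compliance: float  # ml/cmH2O
    airway_resistance: float = 5.0  # cmH2O·s/L
    relaxed_volume_offset: float = 0.0  # ml at zero gauge pressure

    def __post_init__(self) -> None:
        if self.compliance <= 0.0:
            raise DomainError("compliance must be positive")
        if self.airway_resistance <= 0.0:
            raise DomainError("airway resistance must be positive")

    @property
    def compliance_si(self) -> float:
        """m³/Pa."""
        return self.compliance * 1e-6 / PA_PER_CMH2O

    @property
    def airway_resistance_si(self) -> float:
        """Pa·s/m³."""
        return resistance_to_si(self.airway_resistance)

    @property
    def time_constant(self) -> float:
        """R·C in seconds."""
        return self.airway_resistance * self.compliance * 1e-3


def reynolds_number(mass_flow: float, diameter: float,
                    gas: GasProperties = AIR) -> float:
    """Duct Reynolds number Re = 4·|ṁ| / (π·D·μ)."""
    if diameter <= 0.0:
        raise DomainError("diameter must be positive")
    return _kernels.reynolds_kernel(mass_flow, diameter, gas.dynamic_viscosity)


def pipe_pressure_loss(mass_flow: float, pipe: PipeSegment, density: float,
                       gas: GasProperties = AIR) -> float:
    """Signed friction loss across a tubing segment, Pa; odd in mass flow.

    Laminar (Re < 2000) Hagen–Poiseuille, turbulent (Re > 4000)
    Darcy–Weisbach with the Blasius friction factor, linear blend between.
    """
    if density <= 0.0:
        raise DomainError("density must be positive")
    return _kernels.pipe_dp_kernel(mass_flow, pipe.length, pipe.inner_diameter,
                                   density, gas.dynamic_viscosity)


def resistor_pressure_loss(mass_flow: float, resistor: ResistorSpec,
                           density: float, gas: GasProperties = AIR,
                           upstream_diameter: float = 0.022) -> float:
    """Signed composite loss across a reduced-lumen resistor, Pa; odd in flow.

    Contraction + Borda–Carnot expansion minor losses (scaled by
    1/Cd², contraction tapered so both vanish as the lumen approaches the
    tube bore) plus throat pipe friction.  Strictly decreasing in lumen
    diameter at fixed positive flow.
    """
    if density <= 0.0:
        raise DomainError("density must be positive")
    return _kernels.resistor_dp_kernel(
        mass_flow, resistor.lumen_diameter * 1e-3, resistor.throat_length,
        resistor.discharge_coefficient, resistor.contraction_loss_coefficient,
        upstream_diameter, density, gas.dynamic_viscosity)


def lung_flow(airway_pressure_gauge: float, lung_volume_above_relaxed: float,
              lung: LungRC) -> float:
    """Flow into the lung, L/s, for an applied airway pressure.

    dV/dt = (P_aw − V/C) / R_aw: elastic recoil opposes the airway pressure
    and the dashpot limits the rate.  Arguments in cmH₂O and ml.
    """
    recoil = lung_volume_above_relaxed / lung.compliance  # cmH2O
    return (airway_pressure_gauge - recoil) / lung.airway_resistance
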