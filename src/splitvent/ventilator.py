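"""Ventilator boundary conditions: PC and VC setpoint waveforms.

Pressure-controlled (PC) ventilation drives the circuit with a pulse-wave
pressure source cycling between PIP and PEEP; volume-controlled (VC)
ventilation delivers a rectangular inspiratory flow sized to the target
tidal volume and references expiration to PEEP.  Ideal square transitions
are softened by a configurable rise time so the circuit ODE stays
non-stiff at the switch points, mirroring the slew of real machines.
"""

from __future__ import annotations

from dataclasses import dataclass

from .gas import DomainError
from .units import PA_PER_CMH2O


class UsageError(RuntimeError):
    """Operation called for the wrong ventilation mode."""


@dataclass(frozen=True)
class VentilatorSettings:
    """Mode and cycling parameters, clinical units.

    ie_ratio is the (inspiratory, expiratory) pair, e.g. (1, 2) for 1:2.
    target_tidal_volume (ml) is required in VC mode and ignored in PC.
    """

    mode: str = "PC"
    pip: float = 20.0  # cmH2O
    peep: float = 5.0  # cmH2O
    respiratory_rate: float = 20.0  # breaths/min
    ie_ratio: tuple[float, float] = (1.0, 2.0)
    target_tidal_volume: float | None = None  # ml
    pressure_rise_time: float = 0.05  # s

    def __post_init__(self) -> None:
        if self.mode not in ("PC", "VC"):
            raise DomainError(f"unknown ventilation mode {self.mode!r}")
        if self.peep < 0.0:
            raise DomainError("PEEP must be non-negative")
        if self.pip < self.peep:
            raise DomainError("PIP must be >= PEEP")
        if self.respiratory_rate <= 0.0:
            raise DomainError("respiratory rate must be positive")
        if self.ie_ratio[0] <= 0.0 or self.ie_ratio[1] <= 0.0:
            raise DomainError("both I:E parts must be positive")
        if self.mode == "VC" and not (self.target_tidal_volume or 0.0) > 0.0:
            raise DomainError("VC mode requires target_tidal_volume > 0")
        if self.pressure_rise_time <= 0.0:
            raise DomainError("rise time must be positive")
        period, t_insp = breath_timing(self)
        if self.pressure_rise_time > 0.4 * min(t_insp, period - t_insp):
            raise DomainError("rise time too long for the breath timing")

    @property
    def pip_pa(self) -> float:
        return self.pip * PA_PER_CMH2O

    @property
    def peep_pa(self) -> float:
        return self.peep * PA_PER_CMH2O


def breath_timing(settings: VentilatorSettings) -> tuple[float, float]:
    """(breath period, inspiratory time) in seconds.

    period = 60/RR; T_insp = period · I/(I+E).
    """
    period = 60.0 / settings.respiratory_rate
    i, e = settings.ie_ratio
    return period, period * i / (i + e)


def pressure_setpoint(t: float, settings: VentilatorSettings) -> float:
    """PC source pressure at time t, cmH₂O gauge; bounded in [PEEP, PIP]."""
    if settings.mode != "PC":
        raise UsageError("pressure_setpoint requires PC mode")
    period, t_insp = breath_timing(settings)
    tau = t % period
    rise = settings.pressure_rise_time
    if tau < rise:
        return settings.peep + (settings.pip - settings.peep) * tau / rise
    if tau < t_insp:
        return settings.pip
    if tau < t_insp + rise:
        return settings.pip - (settings.pip - settings.peep) * (tau - t_insp) / rise
    return settings.peep


def flow_setpoint(t: float, settings: VentilatorSettings) -> float:
    """VC inspiratory flow at time t, L/s (ideal rectangle).

    Q = target_tidal_volume / T_insp during inspiration, 0 during expiration
    (the expiratory side is referenced to PEEP).  The simulation kernel uses
    the same profile with rise-time ramps whose plateau is scaled so the
    per-breath volume integral stays exactly at the target.
    """
    if settings.mode != "VC":
        raise UsageError("flow_setpoint requires VC mode")
    period, t_insp = breath_timing(settings)
    tau = t % period
    if tau < t_insp:
        return settings.target_tidal_volume / t_insp * 1e-3  # ml/s -> L/s
    return 0.0


def vc_plateau_flow(settings: VentilatorSettings) -> float:
    """Plateau of the ramped VC profile, m³/s, volume-conserving.

    A trapezoid with ramps of the rise time has area Q·(T_insp − rise), so
    the plateau is target / (T_insp − rise).
    """
    _, t_insp = breath_timing(settings)
    return settings.target_tidal_volume * 1e-6 / (t_insp - settings.pressure_rise_time)
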