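"""Unit conversions between SI and clinical respiratory units.

Everything inside the solver is SI (Pa, kg, m³, s); every public interface
speaks clinical units (cmH₂O, ml, L/s or L/min, mm). The conversion constants
are exact definitions, so round trips are lossless to machine precision.
"""

from __future__ import annotations

CMH2O_PER_PA = 1.0 / 98.0665
PA_PER_CMH2O = 98.0665
PA_PER_MMHG = 133.322

_TO_PA = {
    "Pa": 1.0,
    "cmH2O": PA_PER_CMH2O,
    "mmHg": PA_PER_MMHG,
}


class UnitError(ValueError):
    """Unknown unit name in a conversion request."""


def convert_pressure(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a pressure between Pa, cmH2O and mmHg.

    Gauge vs absolute is the caller's business; this is a pure scale factor
    (1 cmH2O = 98.0665 Pa, 1 mmHg = 133.322 Pa).
    """
    try:
        f = _TO_PA[from_unit]
    except KeyError:
        raise UnitError(f"unknown pressure unit {from_unit!r}; "
                        f"expected one of {sorted(_TO_PA)}") from None
    try:
        t = _TO_PA[to_unit]
    except KeyError:
        raise UnitError(f"unknown pressure unit {to_unit!r}; "
                        f"expected one of {sorted(_TO_PA)}") from None
    return value * f / t


def cmh2o_to_pa(value: float) -> float:
    return value * PA_PER_CMH2O


def pa_to_cmh2o(value: float) -> float:
    return value * CMH2O_PER_PA


def ml_to_m3(value: float) -> float:
    return value * 1e-6


def m3_to_ml(value: float) -> float:
    return value * 1e6


def lps_to_m3s(value: float) -> float:
    """Litres per second to m³/s."""
    return value * 1e-3


def m3s_to_lpm(value: float) -> float:
    """m³/s to litres per minute."""
    return value * 6e4


def compliance_to_si(ml_per_cmh2o: float) -> float:
    """ml/cmH₂O → m³/Pa."""
    return ml_per_cmh2o * 1e-6 / PA_PER_CMH2O


def resistance_to_si(cmh2o_s_per_l: float) -> float:
    """cmH₂O·s/L → Pa·s/m³."""
    return cmh2o_s_per_l * PA_PER_CMH2O / 1e-3
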