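"""Resistor selection logic: the decision-support layer over the simulator.

Given two patient profiles and shared ventilator settings, simulate every
candidate resistor (always placed on the higher-compliance patient's limb,
where it reduces the tidal-volume differential) plus the no-resistor
baseline, and select the candidate that best meets the chosen objective.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .components import EttSpec, LungRC, ResistorSpec
from .gas import DomainError
from .metrics import pressure_extrema, tidal_volume_per_cycle
from .network import Network, NumericalError, two_patient_topology
from .sweep import DEFAULT_TEMPLATE, ScenarioTemplate
from .ventilator import VentilatorSettings


class SelectionError(RuntimeError):
    """No converged candidate row to select from."""


class UnsafeModeError(RuntimeError):
    """VC-mode pairing requested without the explicit unsafe opt-in."""


VC_WARNING = ("volume-controlled splitting couples the two patients: a "
              "resistance change on one limb raises pressures and volumes "
              "delivered to BOTH patients and can be dangerous; prefer "
              "pressure-controlled mode")


@dataclass(frozen=True)
class PatientProfile:
    """Per-patient inputs the clinician knows at the bedside."""

    compliance: float  # ml/cmH2O
    ett_diameter: float = 7.5  # mm
    target_tidal_volume: float | None = None  # ml
    airway_resistance: float = 5.0  # cmH2O·s/L

    def __post_init__(self) -> None:
        if self.compliance <= 0.0:
            raise DomainError("compliance must be positive")


@dataclass
class Recommendation:
    """Candidate table plus the selected row.

    ``table`` has one row per resistor option (including none), with the
    predicted steady-state tidal volumes and maximum distal pressures for
    both patients and the objective score; exactly one converged row has
    ``selected = True``.
    """

    table: pd.DataFrame
    objective: str
    resistor_limb: str

    @property
    def selected(self) -> pd.Series:
        sel = self.table[self.table["selected"]]
        if len(sel) != 1:
            raise SelectionError("expected exactly one selected row")
        return sel.iloc[0]

    def to_json(self, **kwargs) -> str:
        payload = {
            "objective": self.objective,
            "resistor_limb": self.resistor_limb,
            "options": json.loads(self.table.to_json(orient="records")),
        }
        return json.dumps(payload, **kwargs)

    def to_text(self) -> str:
        df = self.table.copy()
        df["resistor_mm"] = df["resistor_mm"].map(
            lambda v: "none" if pd.isna(v) else f"{v:g}")
        cols = ["resistor_mm", "tv_A_ml", "tv_B_ml", "pmax_A_cmH2O",
                "pmax_B_cmH2O", "objective_score", "selected"]
        return df[cols].to_string(index=False, float_format=lambda v: f"{v:9.1f}")


def _effective_lumen(value: float) -> float:
    """Sort key treating 'no resistor' as the full 22 mm bore."""
    return 22.0 if (value is None or (isinstance(value, float) and math.isnan(value))) else value


def predict_pair(patient_a: PatientProfile, patient_b: PatientProfile,
                 settings: VentilatorSettings,
                 resistor_options: list[float] = (3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0),
                 objective: str = "equalize",
                 template: ScenarioTemplate = DEFAULT_TEMPLATE,
                 allow_unsafe_vc: bool = False) -> Recommendation:
    """Predict TV/Pmax per resistor option and select the best candidate.

    The resistor is assigned to the higher-compliance patient's limb.  VC
    mode is refused unless ``allow_unsafe_vc`` is set, because a resistor
    change then feeds back on both patients.
    """
    if settings.mode == "VC":
        if not allow_unsafe_vc:
            raise UnsafeModeError(VC_WARNING)
        warnings.warn(VC_WARNING, stacklevel=2)

    limb = "B" if patient_b.compliance >= patient_a.compliance else "A"
    options: list[float | None] = [None]
    options += sorted({float(v) for v in resistor_options})

    rows = []
    for opt in options:
        resistor = None if opt is None else ResistorSpec(lumen_diameter=opt)
        topo = two_patient_topology(
            lung_a=LungRC(patient_a.compliance,
                          airway_resistance=patient_a.airway_resistance),
            lung_b=LungRC(patient_b.compliance,
                          airway_resistance=patient_b.airway_resistance),
            ett_a=EttSpec(patient_a.ett_diameter),
            ett_b=EttSpec(patient_b.ett_diameter),
            resistor=resistor, resistor_limb=limb,
            limb_length=template.limb_length,
            filters=template.filters, valves=template.valves)
        net = Network(topo, settings)
        try:
            wf, used = net.run_to_steady_state(
                max_cycles=template.max_cycles, tol=template.steady_tol,
                rtol=template.rtol, sample_hz=template.sample_hz)
            tv_a = tidal_volume_per_cycle(wf, "A")[-1]
            tv_b = tidal_volume_per_cycle(wf, "B")[-1]
            pa, _ = pressure_extrema(wf, patient="A")
            pb, _ = pressure_extrema(wf, patient="B")
            rows.append({"resistor_mm": opt, "assigned_limb": limb,
                         "tv_A_ml": tv_a, "tv_B_ml": tv_b,
                         "pmax_A_cmH2O": pa, "pmax_B_cmH2O": pb,
                         "cycles_used": used, "converged": wf.converged})
        except NumericalError:
            rows.append({"resistor_mm": opt, "assigned_limb": limb,
                         "tv_A_ml": float("nan"), "tv_B_ml": float("nan"),
                         "pmax_A_cmH2O": float("nan"),
                         "pmax_B_cmH2O": float("nan"),
                         "cycles_used": 0, "converged": False})
    table = pd.DataFrame(rows)
    rec = Recommendation(table=table, objective=objective, resistor_limb=limb)
    select_resistor(rec, objective=objective,
                    targets=(patient_a.target_tidal_volume,
                             patient_b.target_tidal_volume))
    return rec


def select_resistor(recommendation: Recommendation, objective: str = "equalize",
                    targets: tuple[float | None, float | None] = (None, None)
                    ) -> pd.Series:
    """Mark and return the best converged row under the objective.

    ``equalize`` minimises |TV_A − TV_B|; ``per-patient-targets`` minimises
    Σ|TV − target| over both patients.  Ties break toward the larger lumen
    (no resistor counting as the full bore).
    """
    table = recommendation.table
    conv = table[table["converged"]]
    if conv.empty:
        raise SelectionError("no converged candidate rows")
    if objective == "equalize":
        score = (conv["tv_A_ml"] - conv["tv_B_ml"]).abs()
    elif objective == "per-patient-targets":
        ta, tb = targets
        if ta is None or tb is None:
            raise DomainError("per-patient-targets needs both target volumes")
        score = (conv["tv_A_ml"] - ta).abs() + (conv["tv_B_ml"] - tb).abs()
    else:
        raise DomainError(f"unknown objective {objective!r}")

    lumen = conv["resistor_mm"].map(_effective_lumen)
    order = pd.DataFrame({"score": score, "lumen": lumen}).sort_values(
        ["score", "lumen"], ascending=[True, False], kind="mergesort")
    best_idx = order.index[0]

    table["objective_score"] = float("nan")
    table.loc[conv.index, "objective_score"] = score
    table["selected"] = False
    table.loc[best_idx, "selected"] = True
    recommendation.objective = objective
    return table.loc[best_idx]
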