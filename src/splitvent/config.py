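"""Scenario configuration: schema-validated YAML/JSON plus named fixtures.

Every numeric key carries its unit as a suffix; unknown keys are rejected by
name.  Fixtures replicate the benchtop validation circuit (two limbs of 22 mm
tubing, bacterial/viral filters and one-way valves at the source, linear test
lungs) and the bare reduced model.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .components import EttSpec, LungRC, PipeSegment, ResistorSpec
from .network import CircuitTopology, ConfigurationError, Limb, Network
from .ventilator import VentilatorSettings


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class SettingsBlock(_Strict):
    mode: Literal["PC", "VC"] = "PC"
    pip_cmH2O: float = 20.0
    peep_cmH2O: float = 5.0
    rr_per_min: float = 20.0
    ie: tuple[float, float] = (1.0, 2.0)
    target_tv_ml: Optional[float] = None
    rise_time_s: float = 0.05

    @model_validator(mode="after")
    def _check(self):
        if self.pip_cmH2O < self.peep_cmH2O:
            raise ValueError("pip_cmH2O must be >= peep_cmH2O")
        return self

    def to_settings(self) -> VentilatorSettings:
        return VentilatorSettings(
            mode=self.mode, pip=self.pip_cmH2O, peep=self.peep_cmH2O,
            respiratory_rate=self.rr_per_min, ie_ratio=self.ie,
            target_tidal_volume=self.target_tv_ml,
            pressure_rise_time=self.rise_time_s)


class PatientBlock(_Strict):
    compliance_ml_per_cmH2O: float = 30.0
    airway_resistance_cmH2O_s_per_L: float = 5.0
    ett_mm: float = 7.5

    def to_lung(self) -> LungRC:
        return LungRC(self.compliance_ml_per_cmH2O,
                      airway_resistance=self.airway_resistance_cmH2O_s_per_L)


class TubeBlock(_Strict):
    length_m: float = 1.83
    diameter_mm: float = 22.0

    def to_pipe(self) -> PipeSegment:
        return PipeSegment(self.length_m, self.diameter_mm * 1e-3)


class ResistorBlock(_Strict):
    limb: Literal["A", "B"] = "B"
    lumen_mm: float = 4.0
    throat_length_m: float = 0.02
    discharge_coefficient: float = 0.9
    contraction_loss_coefficient: float = 0.4

    def to_resistor(self) -> ResistorSpec:
        return ResistorSpec(
            lumen_diameter=self.lumen_mm, throat_length=self.throat_length_m,
            discharge_coefficient=self.discharge_coefficient,
            contraction_loss_coefficient=self.contraction_loss_coefficient)


class TopologyBlock(_Strict):
    shared_tube: TubeBlock = TubeBlock(length_m=0.5)
    limb_tube: TubeBlock = TubeBlock()
    resistor: Optional[ResistorBlock] = None
    filters: bool = False
    valves: bool = False


class SolverBlock(_Strict):
    rtol: float = 1e-6
    max_cycles: int = 40
    steady_tol_pct: float = 0.5
    sample_hz: float = 1000.0


class PatientsBlock(_Strict):
    A: PatientBlock = PatientBlock()
    B: Optional[PatientBlock] = PatientBlock()


class ScenarioConfig(_Strict):
    """Validated scenario: circuit, ventilator, patients and solver options."""

    settings: SettingsBlock = SettingsBlock()
    patients: PatientsBlock = PatientsBlock()
    topology: TopologyBlock = TopologyBlock()
    solver: SolverBlock = SolverBlock()

    def to_topology(self) -> CircuitTopology:
        t = self.topology
        res = t.resistor.to_resistor() if t.resistor is not None else None
        res_limb = t.resistor.limb if t.resistor is not None else None
        limb_a = Limb(lung=self.patients.A.to_lung(), tube=t.limb_tube.to_pipe(),
                      ett=EttSpec(self.patients.A.ett_mm),
                      resistor=res if res_limb == "A" else None)
        limb_b = None
        if self.patients.B is not None:
            limb_b = Limb(lung=self.patients.B.to_lung(),
                          tube=t.limb_tube.to_pipe(),
                          ett=EttSpec(self.patients.B.ett_mm),
                          resistor=res if res_limb == "B" else None)
        elif res_limb == "B":
            raise ConfigurationError("resistor assigned to absent patient B")
        return CircuitTopology(limb_a=limb_a, limb_b=limb_b,
                               shared_tube=t.shared_tube.to_pipe(),
                               filters=t.filters, valves=t.valves)

    def build_network(self) -> Network:
        return Network(self.to_topology(), self.settings.to_settings())

    def to_dict(self) -> dict:
        return self.model_dump(mode="json")

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def load_config(path: str | Path) -> ScenarioConfig:
    """Read and validate a YAML or JSON scenario file.

    Unknown keys are rejected with the offending key named; defaults fill
    everything omitted.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    try:
        return ScenarioConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc


FIXTURE_NAMES = ("benchtop-fig1c-6ft", "benchtop-fig1c-12ft", "plain-split",
                 "single-patient")


def fixture(name: str, compliance_a: float = 18.0,
            compliance_b: float = 35.0) -> ScenarioConfig:
    """Named scenario fixtures.

    The ``benchtop-fig1c-*`` fixtures emulate the validation circuit: two
    limbs (6 ft or 12 ft of 22 mm tubing), filters + one-way valves at the
    source, and linear test lungs whose low/medium compliance settings are
    selectable (defaults 18 and 35 ml/cmH₂O as measured on the bench).
    ``plain-split`` is the bare reduced model (source → junction → two
    limbs, compliances 30 and 75 ml/cmH₂O); ``single-patient`` is the
    degenerate one-limb circuit.
    """
    if name == "benchtop-fig1c-6ft":
        return ScenarioConfig(
            patients=PatientsBlock(
                A=PatientBlock(compliance_ml_per_cmH2O=compliance_a),
                B=PatientBlock(compliance_ml_per_cmH2O=compliance_b)),
            topology=TopologyBlock(limb_tube=TubeBlock(length_m=1.83),
                                   filters=True, valves=True))
    if name == "benchtop-fig1c-12ft":
        return ScenarioConfig(
            patients=PatientsBlock(
                A=PatientBlock(compliance_ml_per_cmH2O=compliance_a),
                B=PatientBlock(compliance_ml_per_cmH2O=compliance_b)),
            topology=TopologyBlock(limb_tube=TubeBlock(length_m=3.66),
                                   filters=True, valves=True))
    if name == "plain-split":
        return ScenarioConfig(
            patients=PatientsBlock(
                A=PatientBlock(compliance_ml_per_cmH2O=30.0),
                B=PatientBlock(compliance_ml_per_cmH2O=75.0)))
    if name == "single-patient":
        return ScenarioConfig(
            patients=PatientsBlock(A=PatientBlock(compliance_ml_per_cmH2O=30.0),
                                   B=None))
    raise ConfigurationError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
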