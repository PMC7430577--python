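"""Parameter-space enumeration, batch simulation, and grid-resolution audit.

The clinical decision-support table is produced by sweeping seven scenario
dimensions (PIP, PEEP, I:E, respiratory rate, per-patient compliance and ETT
diameter, resistor lumen).  ``build_grid``/``run_sweep`` enumerate and
simulate scenarios deterministically; ``step_size_audit`` measures how much
the predicted tidal volume moves when a single dimension is perturbed by one
grid step, the criterion used to judge whether the grid is fine enough.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Iterator

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .components import EttSpec, LungRC, ResistorSpec
from .metrics import pressure_extrema, tidal_volume_per_cycle
from .network import (ConfigurationError, Network, NumericalError,
                      two_patient_topology)
from .ventilator import VentilatorSettings

# declared dimension order: row ordering is lexicographic over these
DIMENSIONS = ("pip", "peep", "ie", "rr", "compliance_a", "compliance_b",
              "ett_a", "ett_b", "resistor")

# dimensions the audit reports on (compliance and ETT are one physical
# parameter each; the audited patient is chosen per sample)
AUDIT_DIMENSIONS = ("pip", "peep", "ie", "rr", "compliance", "ett", "resistor")


@dataclass(frozen=True)
class Constraint:
    """Named predicate over a subset of dimensions."""

    name: str
    dims: tuple[str, ...]
    fn: Callable[..., bool]

    def ok(self, scenario: dict) -> bool:
        return self.fn(**{d: scenario[d] for d in self.dims})


MIN_DRIVING_PRESSURE = Constraint(
    "min_driving_pressure", ("pip", "peep"),
    lambda pip, peep: pip - peep >= 5.0)


@dataclass(frozen=True)
class SweepGrid:
    """Per-dimension value lists plus constraint predicates.

    ``resistor`` entries are lumen diameters in mm, with ``None`` meaning no
    resistor installed; ``ie`` entries are (I, E) tuples.
    """

    pip: tuple[float, ...]
    peep: tuple[float, ...]
    ie: tuple[tuple[float, float], ...]
    rr: tuple[float, ...]
    compliance_a: tuple[float, ...]
    compliance_b: tuple[float, ...]
    ett_a: tuple[float, ...]
    ett_b: tuple[float, ...]
    resistor: tuple[float | None, ...]
    constraints: tuple[Constraint, ...] = (MIN_DRIVING_PRESSURE,)

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            vals = getattr(self, dim)
            if len(vals) == 0:
                raise ConfigurationError(f"dimension {dim!r} is empty")
            if len(set(vals)) != len(vals):
                raise ConfigurationError(f"dimension {dim!r} has duplicates")

    def values(self, dim: str) -> tuple:
        return getattr(self, dim)

    @property
    def unconstrained_size(self) -> int:
        return math.prod(len(self.values(d)) for d in DIMENSIONS)

    @property
    def size(self) -> int:
        """Number of admissible scenarios (constraint-filtered product).

        Constraints declare which dimensions they touch, so the count only
        enumerates the sub-product of constrained dimensions.
        """
        cdims = sorted({d for c in self.constraints for d in c.dims},
                       key=DIMENSIONS.index)
        free = math.prod(len(self.values(d)) for d in DIMENSIONS
                         if d not in cdims)
        if not cdims:
            return free
        n_ok = 0
        for combo in itertools.product(*(self.values(d) for d in cdims)):
            scenario = dict(zip(cdims, combo))
            if all(c.fn(**{d: scenario[d] for d in c.dims})
                   for c in self.constraints):
                n_ok += 1
        return free * n_ok

    def admissible(self, scenario: dict) -> bool:
        return all(c.ok(scenario) for c in self.constraints)

    def scenarios(self) -> Iterator[dict]:
        """Admissible scenarios in lexicographic order over DIMENSIONS."""
        for combo in itertools.product(*(self.values(d) for d in DIMENSIONS)):
            scenario = dict(zip(DIMENSIONS, combo))
            if self.admissible(scenario):
                yield scenario


def build_grid(pip, peep, ie, rr, compliance_a, compliance_b, ett_a, ett_b,
               resistor, constraints: tuple[Constraint, ...] = (MIN_DRIVING_PRESSURE,),
               ) -> SweepGrid:
    """Build a sweep grid from per-dimension value lists (sorted, unique)."""
    def prep(vals, key=None):
        return tuple(sorted(set(vals), key=key))

    return SweepGrid(
        pip=prep(pip), peep=prep(peep),
        ie=tuple(sorted({tuple(v) for v in ie}, key=lambda v: v[1] / v[0])),
        rr=prep(rr),
        compliance_a=prep(compliance_a), compliance_b=prep(compliance_b),
        ett_a=prep(ett_a), ett_b=prep(ett_b),
        resistor=tuple(sorted(set(resistor),
                              key=lambda v: math.inf if v is None else v)),
        constraints=constraints)


def default_grid() -> SweepGrid:
    """The package's default seven-dimensional grid.

    Spans every operating point used in the validation scenarios (PIP 20/28,
    PEEP 5/8, RR 15–30, ETT 6–8.5 mm, resistors 3.0–6.0 mm, compliances
    18–75 ml/cmH₂O) with clinically conventional steps; driving pressure is
    constrained to at least 5 cmH₂O.
    """
    compliances = tuple(float(v) for v in range(10, 101, 5))
    etts = (6.0, 6.5, 7.0, 7.5, 8.0, 8.5)
    return build_grid(
        pip=[float(v) for v in range(12, 41, 2)],
        peep=[float(v) for v in range(5, 21)],
        ie=[(1.0, 1.0), (1.0, 1.5), (1.0, 2.0), (1.0, 3.0)],
        rr=[float(v) for v in range(10, 36, 5)],
        compliance_a=compliances, compliance_b=compliances,
        ett_a=etts, ett_b=etts,
        resistor=[None, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0])


@dataclass(frozen=True)
class ScenarioTemplate:
    """Everything a scenario dict does not vary: circuit build + solver."""

    airway_resistance: float = 5.0  # cmH2O·s/L, both patients
    limb_length: float = 1.83  # m
    resistor_limb: str = "B"
    filters: bool = False
    valves: bool = False
    max_cycles: int = 40
    steady_tol: float = 0.005
    rtol: float = 1e-6
    sample_hz: float = 1000.0


DEFAULT_TEMPLATE = ScenarioTemplate()


def scenario_network(scenario: dict,
                     template: ScenarioTemplate = DEFAULT_TEMPLATE) -> Network:
    """Instantiate the circuit + ventilator for one sweep scenario (PC mode)."""
    settings = VentilatorSettings(
        mode="PC", pip=scenario["pip"], peep=scenario["peep"],
        respiratory_rate=scenario["rr"], ie_ratio=tuple(scenario["ie"]))
    resistor = (None if scenario["resistor"] is None
                else ResistorSpec(lumen_diameter=scenario["resistor"]))
    topo = two_patient_topology(
        lung_a=LungRC(scenario["compliance_a"],
                      airway_resistance=template.airway_resistance),
        lung_b=LungRC(scenario["compliance_b"],
                      airway_resistance=template.airway_resistance),
        ett_a=EttSpec(scenario["ett_a"]), ett_b=EttSpec(scenario["ett_b"]),
        resistor=resistor, resistor_limb=template.resistor_limb,
        limb_length=template.limb_length,
        filters=template.filters, valves=template.valves)
    return Network(topo, settings)


@dataclass(frozen=True)
class SweepRecord:
    """One simulated scenario: inputs plus steady-state outputs."""

    scenario: dict
    tv_a: float
    tv_b: float
    pmax_a: float
    pmax_b: float
    cycles_used: int
    converged: bool


def _simulate_scenario(scenario: dict, template: ScenarioTemplate) -> SweepRecord:
    try:
        net = scenario_network(scenario, template)
        wf, used = net.run_to_steady_state(
            max_cycles=template.max_cycles, tol=template.steady_tol,
            rtol=template.rtol, sample_hz=template.sample_hz)
        tv_a = tidal_volume_per_cycle(wf, "A")[-1]
        tv_b = tidal_volume_per_cycle(wf, "B")[-1]
        pa, _ = pressure_extrema(wf, patient="A")
        pb, _ = pressure_extrema(wf, patient="B")
        return SweepRecord(scenario, tv_a, tv_b, pa, pb, used, wf.converged)
    except NumericalError:
        return SweepRecord(scenario, float("nan"), float("nan"),
                           float("nan"), float("nan"), 0, False)


def _records_to_frame(records: list[SweepRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        s = rec.scenario
        rows.append({
            "pip_cmH2O": s["pip"], "peep_cmH2O": s["peep"],
            "ie_insp": s["ie"][0], "ie_exp": s["ie"][1], "rr_per_min": s["rr"],
            "compliance_A_ml_per_cmH2O": s["compliance_a"],
            "compliance_B_ml_per_cmH2O": s["compliance_b"],
            "ett_A_mm": s["ett_a"], "ett_B_mm": s["ett_b"],
            "resistor_mm": (np.nan if s["resistor"] is None else s["resistor"]),
            "tv_A_ml": rec.tv_a, "tv_B_ml": rec.tv_b,
            "pmax_A_cmH2O": rec.pmax_a, "pmax_B_cmH2O": rec.pmax_b,
            "cycles_used": rec.cycles_used, "converged": rec.converged,
        })
    return pd.DataFrame(rows)


def run_sweep(grid: SweepGrid, template: ScenarioTemplate = DEFAULT_TEMPLATE,
              n_jobs: int = 1) -> pd.DataFrame:
    """Simulate every admissible scenario; one row per scenario.

    Output order is the grid's lexicographic scenario order regardless of
    worker count; failed scenarios are kept with ``converged = False``.
    """
    scenarios = list(grid.scenarios())
    if n_jobs == 1:
        records = [_simulate_scenario(s, template) for s in scenarios]
    else:
        records = Parallel(n_jobs=n_jobs)(
            delayed(_simulate_scenario)(s, template) for s in scenarios)
    return _records_to_frame(records)


# -- step-size audit -------------------------------------------------------

def _perturb_index(i: int, n: int) -> int:
    """One grid step: up, or down from the top of the list."""
    return i + 1 if i + 1 < n else i - 1


def _tv_change_pct(base: SweepRecord, pert: SweepRecord) -> float:
    worst = 0.0
    any_ref = False
    for tv0, tv1 in ((base.tv_a, pert.tv_a), (base.tv_b, pert.tv_b)):
        if np.isfinite(tv0) and tv0 > 1e-9 and np.isfinite(tv1):
            worst = max(worst, 100.0 * abs(tv1 - tv0) / tv0)
            any_ref = True
    return worst if any_ref else 0.0


def step_size_audit(grid: SweepGrid,
                    template: ScenarioTemplate = DEFAULT_TEMPLATE,
                    sample_count: int = 100, seed: int = 42,
                    dims: tuple[str, ...] = AUDIT_DIMENSIONS,
                    exhaustive: bool = False,
                    n_jobs: int = 1) -> tuple[dict[str, float], pd.DataFrame]:
    """Largest single-step tidal-volume change per dimension, percent.

    For each audited dimension, sample ``sample_count`` admissible grid
    points (seeded, reproducible), move that dimension by one grid step,
    simulate both scenarios to steady state, and record
    100·|ΔTV|/TV (worst patient).  Returns ({dimension: max percent}, detail
    frame).  ``compliance`` and ``ett`` perturb one patient's value, chosen
    by the seeded RNG per sample.  With ``exhaustive=True`` every admissible
    grid point is audited instead of a sample (small grids only).
    """
    rng = np.random.default_rng(seed)
    jobs: list[tuple[str, dict, dict]] = []  # (dim, base, perturbed)

    def add_job(dim: str, scenario: dict, grid_dim: str) -> None:
        vals = grid.values(grid_dim)
        if len(vals) < 2:
            return
        i = vals.index(scenario[grid_dim])
        pert = dict(scenario)
        pert[grid_dim] = vals[_perturb_index(i, len(vals))]
        if grid.admissible(pert):
            jobs.append((dim, scenario, pert))

    if exhaustive:
        for scenario in grid.scenarios():
            for dim in dims:
                gdims = ([f"{dim}_a", f"{dim}_b"]
                         if dim in ("compliance", "ett") else [dim])
                for gd in gdims:
                    add_job(dim, scenario, gd)
    else:
        for dim in dims:
            made = 0
            attempts = 0
            while made < sample_count and attempts < sample_count * 200:
                attempts += 1
                scenario = {d: grid.values(d)[rng.integers(len(grid.values(d)))]
                            for d in DIMENSIONS}
                if not grid.admissible(scenario):
                    continue
                if dim in ("compliance", "ett"):
                    gd = f"{dim}_{'a' if rng.integers(2) == 0 else 'b'}"
                else:
                    gd = dim
                before = len(jobs)
                add_job(dim, scenario, gd)
                made += len(jobs) - before

    def run_pair(job):
        dim, base, pert = job
        rb = _simulate_scenario(base, template)
        rp = _simulate_scenario(pert, template)
        return dim, base, pert, _tv_change_pct(rb, rp), rb.converged and rp.converged

    if n_jobs == 1:
        results = [run_pair(j) for j in jobs]
    else:
        results = Parallel(n_jobs=n_jobs)(delayed(run_pair)(j) for j in jobs)

    detail = pd.DataFrame(
        [{"dimension": dim, "tv_change_pct": pct, "converged": ok,
          **{f"base_{k}": (str(v) if k == "ie" else v) for k, v in base.items()},
          **{f"pert_{k}": (str(v) if k == "ie" else v) for k, v in pert.items()}}
         for dim, base, pert, pct, ok in results])
    maxima = {dim: 0.0 for dim in dims}
    for dim, _, _, pct, _ in results:
        maxima[dim] = max(maxima[dim], pct)
    return maxima, detail
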