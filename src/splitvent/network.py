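"""Assemble the split circuit into an ODE system and integrate breath cycles.

The circuit is ventilator source → (optional filter / one-way valve pair) →
shared tubing → splitter junction → per patient: (optional resistor) → limb
tubing → endotracheal tube → single-compartment lung.  Each tubing segment
contributes one compressible gas node; connection flows are solved from the
momentum balance (friction + minor losses + the convective term) by monotone
scalar root finding at every RHS evaluation, and node pressures evolve from
the mass balance ∂M/∂p·dp/dt (+ ∂M/∂T·dT/dt in the non-isothermal mode) =
Σṁ.  Integration uses LSODA (stiff-capable) cycle by cycle until the
per-patient tidal volumes settle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import odeint

from . import _kernels as K
from .components import EttSpec, LungRC, PipeSegment, ResistorSpec
from .gas import AIR, GasProperties
from .units import PA_PER_CMH2O, m3s_to_lpm, resistance_to_si
from .ventilator import VentilatorSettings, breath_timing, vc_plateau_flow


class ConfigurationError(ValueError):
    """Inconsistent or unsupported circuit description."""


class NumericalError(RuntimeError):
    """The ODE integrator failed to converge."""


# spec'd default element resistances for the benchtop accessories, cmH2O·s/L
FILTER_RESISTANCE = 0.5
VALVE_FORWARD_RESISTANCE = 0.1
VALVE_SMOOTHING_CMH2O = 0.05

DEFAULT_TUBE_DIAMETER = 0.022  # m, standard 22 mm circuit tubing
DEFAULT_LIMB_LENGTH = 1.83     # m (6 ft)
DEFAULT_SHARED_LENGTH = 0.5    # m


@dataclass(frozen=True)
class Limb:
    """One patient branch: optional resistor, tubing, ETT, lung."""

    lung: LungRC
    tube: PipeSegment = PipeSegment(DEFAULT_LIMB_LENGTH, DEFAULT_TUBE_DIAMETER)
    ett: EttSpec = EttSpec()
    resistor: ResistorSpec | None = None


@dataclass(frozen=True)
class CircuitTopology:
    """Fixed two-limb (or degenerate single-limb) split-circuit layout.

    ``filters``/``valves`` switch on the benchtop accessories: a
    viral/bacterial filter and a one-way valve pair at the source, modeled
    as a directional linear resistance (forward = inspiratory path,
    reverse = expiratory path) smoothed over a small pressure band to keep
    the RHS continuous.  Both default off, matching the reduced model.
    """

    limb_a: Limb
    limb_b: Limb | None
    shared_tube: PipeSegment = PipeSegment(DEFAULT_SHARED_LENGTH,
                                           DEFAULT_TUBE_DIAMETER)
    filters: bool = False
    valves: bool = False

    def __post_init__(self) -> None:
        if self.limb_b is not None:
            if self.limb_a.resistor is not None and self.limb_b.resistor is not None:
                raise ConfigurationError(
                    "a resistor may be installed on at most one limb per scenario")

    @property
    def patients(self) -> tuple[str, ...]:
        return ("A", "B") if self.limb_b is not None else ("A",)

    def limb(self, patient: str) -> Limb:
        if patient == "A":
            return self.limb_a
        if patient == "B" and self.limb_b is not None:
            return self.limb_b
        raise ConfigurationError(f"unknown patient {patient!r}")


def two_patient_topology(lung_a: LungRC, lung_b: LungRC,
                         ett_a: EttSpec = EttSpec(), ett_b: EttSpec = EttSpec(),
                         resistor: ResistorSpec | None = None,
                         resistor_limb: str = "B",
                         limb_length: float = DEFAULT_LIMB_LENGTH,
                         filters: bool = False, valves: bool = False) -> CircuitTopology:
    """Convenience constructor for the standard two-patient split circuit."""
    tube = PipeSegment(limb_length, DEFAULT_TUBE_DIAMETER)
    res_a = resistor if resistor_limb == "A" else None
    res_b = resistor if resistor_limb == "B" else None
    if resistor is not None and resistor_limb not in ("A", "B"):
        raise ConfigurationError(f"unknown resistor limb {resistor_limb!r}")
    return CircuitTopology(
        limb_a=Limb(lung=lung_a, tube=tube, ett=ett_a, resistor=res_a),
        limb_b=Limb(lung=lung_b, tube=tube, ett=ett_b, resistor=res_b),
        filters=filters, valves=valves)


@dataclass
class WaveformSeries:
    """Sampled simulation output in clinical units.

    Pressures are gauge cmH₂O per gas node; volumes are per-patient lung
    volumes above the relaxed state, ml; flows (L/min, positive toward the
    patient) are recovered lazily from the stored states by re-solving the
    connection momentum balances.
    """

    time: np.ndarray
    pressures: dict[str, np.ndarray]
    volumes: dict[str, np.ndarray]
    cycle_starts: np.ndarray  # index of each cycle's first sample
    period: float
    respiratory_rate: float
    converged: bool = True
    _states: np.ndarray | None = field(default=None, repr=False)
    _params: np.ndarray | None = field(default=None, repr=False)
    _flows: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.time)
        for arr in list(self.pressures.values()) + list(self.volumes.values()):
            if len(arr) != n:
                raise ValueError("waveform arrays must share one time base")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_starts)

    @property
    def patients(self) -> tuple[str, ...]:
        return tuple(self.volumes.keys())

    @property
    def flows(self) -> dict[str, np.ndarray]:
        if self._flows is None:
            if self._states is None or self._params is None:
                raise ValueError("flow recovery needs the stored solver states")
            mf = K.recover_flows_kernel(self.time, self._states, self._params)
            rs, t_ref = self._params[K.P_RS], self._params[K.P_T]
            rho = {"source": self._states[:, 0] / (rs * t_ref),
                   "limb_A": self._states[:, 1] / (rs * t_ref),
                   "limb_B": self._states[:, 2] / (rs * t_ref)}
            if self._params[K.P_ENERGY] != 0.0:
                rho["source"] = self._states[:, 0] / (rs * self._states[:, 8])
                rho["limb_A"] = self._states[:, 1] / (rs * self._states[:, 9])
                rho["limb_B"] = self._states[:, 2] / (rs * self._states[:, 10])
            out = {"source": m3s_to_lpm(mf[:, 0] / rho["source"]),
                   "limb_A": m3s_to_lpm(mf[:, 1] / rho["limb_A"]),
                   "lung_A": m3s_to_lpm(mf[:, 3] / rho["limb_A"])}
            if "B" in self.volumes:
                out["limb_B"] = m3s_to_lpm(mf[:, 2] / rho["limb_B"])
                out["lung_B"] = m3s_to_lpm(mf[:, 4] / rho["limb_B"])
            self._flows = out
        return self._flows

    def cycle_bounds(self, cycle: int) -> tuple[int, int]:
        """Half-open sample range [start, end) of one cycle."""
        start = self.cycle_starts[cycle]
        end = (self.cycle_starts[cycle + 1]
               if cycle + 1 < len(self.cycle_starts) else len(self.time))
        return int(start), int(end)

    def to_dataframe(self, with_flows: bool = True):
        import pandas as pd

        cols = {"time_s": self.time}
        cycle_idx = np.zeros(len(self.time), dtype=int)
        for c in range(self.n_cycles):
            s, e = self.cycle_bounds(c)
            cycle_idx[s:e] = c
        cols["cycle"] = cycle_idx
        for node, arr in self.pressures.items():
            cols[f"p_{node}_cmH2O"] = arr
        if with_flows:
            for limb, arr in self.flows.items():
                cols[f"q_{limb}_Lmin"] = arr
        for pat, arr in self.volumes.items():
            cols[f"v_{pat}_ml"] = arr
        return pd.DataFrame(cols)


class Network:
    """Compiled ODE descriptor for one circuit + ventilator configuration."""

    def __init__(self, topology: CircuitTopology, settings: VentilatorSettings,
                 gas: GasProperties = AIR, isothermal: bool = True):
        self.topology = topology
        self.settings = settings
        self.gas = gas
        self.isothermal = isothermal
        self.params = self._pack()
        self.n_states = K.NSTATE_ISO if isothermal else K.NSTATE_ENERGY

    def _pack(self) -> np.ndarray:
        topo, s, gas = self.topology, self.settings, self.gas
        p = np.zeros(K.NP)
        p[K.P_RS] = gas.specific_gas_constant
        p[K.P_T] = gas.reference_temperature
        p[K.P_MU] = gas.dynamic_viscosity
        p[K.P_PATM] = gas.atmospheric_pressure
        p[K.P_MODE] = 0.0 if s.mode == "PC" else 1.0
        p[K.P_PIP] = s.pip_pa
        p[K.P_PEEP] = s.peep_pa
        period, t_insp = breath_timing(s)
        p[K.P_PERIOD] = period
        p[K.P_TINSP] = t_insp
        p[K.P_RISE] = s.pressure_rise_time
        if s.mode == "VC":
            p[K.P_QVC] = vc_plateau_flow(s)
        r_path = 0.0
        if topo.filters:
            r_path += resistance_to_si(FILTER_RESISTANCE)
        if topo.valves:
            r_path += resistance_to_si(VALVE_FORWARD_RESISTANCE)
        p[K.P_RFWD] = r_path
        p[K.P_RREV] = r_path
        if r_path > 0.0:
            p[K.P_QSM] = VALVE_SMOOTHING_CMH2O * PA_PER_CMH2O / r_path
        p[K.P_LSH] = topo.shared_tube.length
        p[K.P_DSH] = topo.shared_tube.inner_diameter
        p[K.P_VI] = topo.shared_tube.gas_volume
        p[K.P_ENERGY] = 0.0 if self.isothermal else 1.0
        p[K.P_CV] = gas.cv
        for patient, off in (("A", K.LIMB_A), ("B", K.LIMB_B)):
            if patient == "B" and topo.limb_b is None:
                continue
            limb = topo.limb(patient)
            if limb.resistor is not None:
                r = limb.resistor
                p[off + K.L_HASRES] = 1.0
                p[off + K.L_DRES] = r.lumen_diameter * 1e-3
                p[off + K.L_LT] = r.throat_length
                p[off + K.L_CD] = r.discharge_coefficient
                p[off + K.L_KC] = r.contraction_loss_coefficient
            p[off + K.L_LTUBE] = limb.tube.length
            p[off + K.L_DTUBE] = limb.tube.inner_diameter
            p[off + K.L_VNODE] = limb.tube.gas_volume
            p[off + K.L_DETT] = limb.ett.inner_diameter * 1e-3
            p[off + K.L_LETT] = limb.ett.length
            p[off + K.L_RAW] = limb.lung.airway_resistance_si
            p[off + K.L_C] = limb.lung.compliance_si
        p[K.P_HASB] = 1.0 if topo.limb_b is not None else 0.0
        return p

    # -- integration -----------------------------------------------------

    def initial_state(self) -> np.ndarray:
        p = self.params
        y0 = np.zeros(self.n_states)
        p0 = p[K.P_PATM] + p[K.P_PEEP]
        y0[0] = y0[1] = y0[2] = p0
        y0[3] = p[K.LIMB_A + K.L_C] * p[K.P_PEEP]
        y0[4] = p[K.LIMB_B + K.L_C] * p[K.P_PEEP] if p[K.P_HASB] else 0.0
        if not self.isothermal:
            y0[8] = y0[9] = y0[10] = p[K.P_T]
        return y0

    def _atol(self) -> np.ndarray:
        atol = np.array([1e-2, 1e-2, 1e-2, 1e-11, 1e-11, 1e-12, 1e-12, 1e-12,
                         1e-5, 1e-5, 1e-5])
        return atol[:self.n_states]

    def _integrate_cycle(self, y: np.ndarray, k: int, rtol: float,
                         sample_hz: float) -> tuple[np.ndarray, np.ndarray]:
        p = self.params
        period, t_insp, rise = p[K.P_PERIOD], p[K.P_TINSP], p[K.P_RISE]
        n = max(int(round(period * sample_hz)), 20)
        ts = k * period + np.linspace(0.0, period, n + 1)
        tcrit = k * period + np.array([0.0, rise, t_insp - rise, t_insp,
                                       t_insp + rise])
        scr = np.zeros((5, 16))
        sol, info = odeint(K.rhs_kernel, y, ts, args=(p, scr), rtol=rtol,
                           atol=self._atol(), tcrit=tcrit, mxstep=100000,
                           full_output=True, printmessg=False)
        if info["message"] != "Integration successful." or not np.all(
                np.isfinite(sol[-1])):
            raise NumericalError(
                f"LSODA failed in cycle {k}: {info['message']!r}")
        return ts, sol

    def simulate(self, n_cycles: int = 5, rtol: float = 1e-6,
                 sample_hz: float = 1000.0) -> WaveformSeries:
        """Integrate exactly ``n_cycles`` breath cycles from the PEEP state."""
        if n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")
        wf, _ = self._run(n_cycles=n_cycles, min_cycles=n_cycles,
                          tol=None, rtol=rtol, sample_hz=sample_hz)
        return wf

    def run_to_steady_state(self, max_cycles: int = 40, tol: float = 0.005,
                            rtol: float = 1e-6, sample_hz: float = 1000.0,
                            min_cycles: int = 5) -> tuple[WaveformSeries, int]:
        """Simulate until per-patient tidal volumes settle within ``tol``.

        At least ``min_cycles`` (default 5) cycles are always run; if the
        relative cycle-to-cycle tidal-volume change has not dropped below
        ``tol`` by ``max_cycles`` the waveforms are returned flagged
        (``converged = False``) rather than raising.
        """
        if max_cycles < min_cycles:
            raise ConfigurationError("max_cycles must be >= min_cycles")
        return self._run(n_cycles=max_cycles, min_cycles=min_cycles, tol=tol,
                         rtol=rtol, sample_hz=sample_hz)

    def _run(self, n_cycles: int, min_cycles: int, tol: float | None,
             rtol: float, sample_hz: float) -> tuple[WaveformSeries, int]:
        y = self.initial_state()
        chunks_t: list[np.ndarray] = []
        chunks_y: list[np.ndarray] = []
        starts: list[int] = []
        n_samples = 0
        tv_prev: np.ndarray | None = None
        converged = tol is None
        used = n_cycles
        for k in range(n_cycles):
            ts, sol = self._integrate_cycle(y, k, rtol, sample_hz)
            y = sol[-1]
            starts.append(n_samples)
            chunks_t.append(ts[:-1])  # half-open [start, end)
            chunks_y.append(sol[:-1])
            n_samples += len(ts) - 1
            if tol is not None:
                va = sol[:, 3]
                tv = np.array([va.max() - va.min()])
                if self.params[K.P_HASB]:
                    vb = sol[:, 4]
                    tv = np.array([va.max() - va.min(), vb.max() - vb.min()])
                if tv_prev is not None and k + 1 >= min_cycles:
                    delta = np.abs(tv - tv_prev) / np.maximum(tv, 1e-10)
                    if np.all(delta < tol):
                        converged = True
                        used = k + 1
                        break
                tv_prev = tv
        time = np.concatenate(chunks_t)
        states = np.vstack(chunks_y)
        wf = self._to_waveforms(time, states, np.asarray(starts), converged)
        return wf, used

    def _to_waveforms(self, time: np.ndarray, states: np.ndarray,
                      starts: np.ndarray, converged: bool) -> WaveformSeries:
        p = self.params
        patm = p[K.P_PATM]
        pressures = {"shared": (states[:, 0] - patm) / PA_PER_CMH2O,
                     "limb_A": (states[:, 1] - patm) / PA_PER_CMH2O}
        volumes = {"A": states[:, 3] * 1e6}
        if p[K.P_HASB]:
            pressures["limb_B"] = (states[:, 2] - patm) / PA_PER_CMH2O
            volumes["B"] = states[:, 4] * 1e6
        return WaveformSeries(
            time=time, pressures=pressures, volumes=volumes,
            cycle_starts=starts, period=p[K.P_PERIOD],
            respiratory_rate=self.settings.respiratory_rate,
            converged=converged, _states=states, _params=p)


# -- spec-level operation wrappers ----------------------------------------

def build_network(topology: CircuitTopology, settings: VentilatorSettings,
                  gas: GasProperties = AIR, isothermal: bool = True) -> Network:
    """Validate the topology and compile it into an ODE descriptor."""
    return Network(topology, settings, gas=gas, isothermal=isothermal)


def simulate(network: Network, n_cycles: int = 5, rtol: float = 1e-6,
             sample_hz: float = 1000.0) -> WaveformSeries:
    return network.simulate(n_cycles=n_cycles, rtol=rtol, sample_hz=sample_hz)


def run_to_steady_state(network: Network, max_cycles: int = 40,
                        tol: float = 0.005, rtol: float = 1e-6,
                        sample_hz: float = 1000.0) -> tuple[WaveformSeries, int]:
    return network.run_to_steady_state(max_cycles=max_cycles, tol=tol,
                                       rtol=rtol, sample_hz=sample_hz)


def junction_residual(waveforms: WaveformSeries) -> float:
    """Cycle-averaged mass imbalance at the splitter junction, kg/s.

    For each breath cycle, compares the integrated source inflow against the
    integrated limb outflows plus the change in gas mass stored in the
    shared node (the cumulative-mass states are integrated alongside the
    pressures, so this measures true integration-level mass closure, not a
    restatement of the RHS).
    """
    states = waveforms._states
    p = waveforms._params
    if states is None or p is None:
        raise ValueError("junction_residual needs the stored solver states")
    rs = p[K.P_RS]
    worst = 0.0
    for c in range(waveforms.n_cycles):
        s, e = waveforms.cycle_bounds(c)
        e = min(e, len(waveforms.time) - 1)
        if e <= s:
            continue
        d_min = states[e, 5] - states[s, 5]
        d_ma = states[e, 6] - states[s, 6]
        d_mb = states[e, 7] - states[s, 7]
        if p[K.P_ENERGY] != 0.0:
            m0 = p[K.P_VI] * states[s, 0] / (rs * states[s, 8])
            m1 = p[K.P_VI] * states[e, 0] / (rs * states[e, 8])
        else:
            m0 = p[K.P_VI] * states[s, 0] / (rs * p[K.P_T])
            m1 = p[K.P_VI] * states[e, 0] / (rs * p[K.P_T])
        dt = waveforms.time[e] - waveforms.time[s]
        worst = max(worst, abs(d_min - d_ma - d_mb - (m1 - m0)) / dt)
    return worst
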