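"""Clinical breath metrics extracted from simulated (or measured) waveforms."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .gas import DomainError
from .network import ConfigurationError, WaveformSeries


class UsageError(RuntimeError):
    pass


@dataclass(frozen=True)
class PatientBreath:
    tidal_volume: float       # ml
    max_pressure: float       # cmH2O, distal circuit node
    min_pressure: float       # cmH2O
    minute_ventilation: float  # L/min


@dataclass(frozen=True)
class BreathSummary:
    """Last-cycle metrics per patient plus the pair differential.

    minute_ventilation = tidal_volume × RR / 1000 by construction;
    differential_volume_pct is relative to the lower tidal volume.
    """

    patients: dict[str, PatientBreath]
    differential_volume_pct: float | None
    cycles_used: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "patients": {k: asdict(v) for k, v in self.patients.items()},
            "differential_volume_pct": self.differential_volume_pct,
            "cycles_used": self.cycles_used,
            "converged": self.converged,
        }


def tidal_volume_per_cycle(waveforms: WaveformSeries, patient: str) -> list[float]:
    """Per-cycle tidal volume, ml: max − min lung volume over each cycle."""
    if waveforms.n_cycles < 1:
        raise UsageError("need at least one complete cycle")
    if patient not in waveforms.volumes:
        raise ConfigurationError(f"unknown patient {patient!r}")
    v = waveforms.volumes[patient]
    out = []
    for c in range(waveforms.n_cycles):
        s, e = waveforms.cycle_bounds(c)
        win = v[s:e]
        out.append(float(win.max() - win.min()))
    return out


def differential_volume_pct(tv_low: float, tv_high: float) -> float:
    """Excess of the higher tidal volume over the lower, percent."""
    if tv_low <= 0.0:
        raise DomainError("reference tidal volume must be positive")
    return 100.0 * (tv_high - tv_low) / tv_low


def pressure_extrema(waveforms: WaveformSeries, patient: str | None = None,
                     location: str | None = None) -> tuple[float, float]:
    """(max, min) gauge pressure, cmH₂O, at a node over the last full cycle.

    ``location`` names a node ('shared', 'limb_A', 'limb_B'); when omitted it
    defaults to the named patient's distal limb node.
    """
    if location is None:
        if patient is None:
            raise ConfigurationError("give a patient or an explicit node")
        location = f"limb_{patient}"
    if location not in waveforms.pressures:
        raise ConfigurationError(
            f"unknown node {location!r}; have {sorted(waveforms.pressures)}")
    s, e = waveforms.cycle_bounds(waveforms.n_cycles - 1)
    win = waveforms.pressures[location][s:e]
    return float(win.max()), float(win.min())


def pearson_r(predicted: list[float], observed: list[float]) -> float:
    """Product-moment correlation between predicted and observed volumes."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise DomainError("need equal-length vectors with at least 3 points")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        raise DomainError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def summarize(waveforms: WaveformSeries, cycles_used: int | None = None) -> BreathSummary:
    """BreathSummary of the last full cycle of a (steady-state) run."""
    rr = waveforms.respiratory_rate
    patients: dict[str, PatientBreath] = {}
    for pat in waveforms.patients:
        tv = tidal_volume_per_cycle(waveforms, pat)[-1]
        pmax, pmin = pressure_extrema(waveforms, patient=pat)
        patients[pat] = PatientBreath(
            tidal_volume=tv, max_pressure=pmax, min_pressure=pmin,
            minute_ventilation=tv * rr / 1000.0)
    diff = None
    if len(patients) == 2:
        tvs = sorted(p.tidal_volume for p in patients.values())
        if tvs[0] > 0.0:
            diff = differential_volume_pct(tvs[0], tvs[1])
        elif tvs[1] == 0.0:
            diff = 0.0
    return BreathSummary(patients=patients, differential_volume_pct=diff,
                         cycles_used=cycles_used or waveforms.n_cycles,
                         converged=waveforms.converged)


def benchtop_comparison(predicted_ml: list[float], observed_ml: list[float]) -> dict:
    """Soft model-vs-benchtop comparison: correlation and mean error.

    Absolute benchtop tidal volumes can embed effects outside the reduced
    model (circuit gas compression, dynamic test-lung behaviour), so this
    reports agreement statistics rather than gating anything.
    """
    r = pearson_r(predicted_ml, observed_ml)
    x = np.asarray(predicted_ml, dtype=float)
    y = np.asarray(observed_ml, dtype=float)
    return {"pearson_r": r,
            "mean_error_ml": float(np.mean(x - y)),
            "mean_abs_error_ml": float(np.mean(np.abs(x - y))),
            "n": int(x.size)}
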