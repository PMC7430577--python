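# Methods

## Model

`splitvent` simulates a single ventilator shared between two passive patients
through a Y-split breathing circuit, as a lumped compressible gas network:

- **Gas nodes.** Each tubing segment (the shared segment and one per limb)
  is a rigid volume of ideal gas. Its pressure evolves from the mass
  balance ∂M/∂p·dp/dt + ∂M/∂T·dT/dt = Σṁ with M = pV/(RT). In the default
  isothermal mode T is fixed at the reference temperature and the energy
  balance is satisfied identically by the implied wall heat flow. A
  non-isothermal mode (`isothermal=False`) instead advances node pressure
  from the energy balance ∂U/∂p·dp/dt = ΣΦ + Q_H with adiabatic walls
  (Q_H = 0), enthalpy advection Φ = ṁ·c_p·T_upwind, and recovers dT/dt from
  the mass balance. For an ideal gas ∂U/∂T vanishes at fixed p and V, which
  is why the energy equation determines dp/dt directly. The two modes agree
  on tidal volumes to within a few percent at ventilation pressures, which
  is why isothermal is the default.
- **Connections.** Flows between nodes are quasi-steady: at every RHS
  evaluation the signed mass flow through each series connection is solved
  from the momentum relation
  p_up − p_dn = (ṁ/S)²(1/ρ_up − 1/ρ_dn) + Δp_loss(ṁ)
  by safeguarded regula falsi (the loss laws are monotone odd functions;
  flow tolerance ~1e-9 Pa residual). No gas inertance state is carried.
- **Friction.** Darcy–Weisbach with f = 64/Re below Re 2000 (identical to
  Hagen–Poiseuille) and the Blasius correlation f = 0.316·Re^(−1/4) above
  Re 4000, blended linearly in Re between, since circuit Reynolds numbers
  reach ~4000 at peak inspiratory flow.
- **Resistor.** The inline reduced-lumen resistor is a short throat of the
  labelled lumen diameter (interpreted as a *diameter* in mm; one source
  passage says "radius", treated as loose wording): sudden-contraction loss
  K_c(1−σ)·ρv_t²/2 plus Borda–Carnot re-expansion ρ(v_t−v_up)²/2, both
  divided by Cd², plus pipe friction over the throat length. σ is the
  throat/tube area ratio; tapering the contraction coefficient by (1−σ)
  makes the minor losses vanish as the lumen approaches the 22 mm bore, so
  a fully open "resistor" degenerates to a bare tube stub. Defaults:
  throat length 20 mm (the physical part's taper is not dimensioned; this
  is exposed in config), Cd = 0.9, K_c = 0.4. Only the inertial terms carry
  1/Cd², so the open-lumen limit is exact.
- **Lung.** Single compartment, Kelvin–Voigt: P_aw = V/C + R_aw·dV/dt.
  Compliance C in ml/cmH₂O is patient-specific; airway resistance defaults
  to 5 cmH₂O·s/L and is deliberately identical for both patients (differing
  resistances are a second-order effect excluded from this version).
- **Ventilator.** PC mode: a pulse-wave pressure source cycling PEEP→PIP
  with period 60/RR and inspiratory fraction I/(I+E); the ideal square edges
  are replaced by 50 ms linear ramps (real machines slew, and the ODE stays
  non-stiff at the transitions). VC mode: an ideal rectangular inspiratory
  flow Q = TV_target/T_insp (constant-flow profile; a decelerating profile
  would be an alternative) with expiration referenced to PEEP; the ramped
  kernel profile rescales the plateau so the per-breath volume integral is
  exactly the target.

State vector: three node pressures + two lung volumes (+ three node
temperatures in non-isothermal mode) + three cumulative connection masses
used purely for conservation audits. Integration is LSODA (via
`scipy.integrate.odeint`, numba-compiled right-hand side), rtol 1e-6,
cycle-by-cycle with the ramp corners passed as critical times; initial
condition is the PEEP-equilibrated circuit (nodes at PEEP, lung volume
C·PEEP). Waveforms are sampled at 1 kHz; cycle windows are half-open
[start, end); flows are recovered from stored states by re-solving the
momentum balances, so the stored tables stay internally consistent.

Steady state: cycles are run until the per-patient tidal volume changes by
less than 0.5% (relative) between consecutive cycles, with a floor of 5
cycles and a default cap of 40; a run that does not settle is returned
flagged, not raised. Metrics (tidal volume = max−min of the volume trace,
maximum/trough distal pressure, minute ventilation) are taken from the last
full cycle. The tidal-volume differential between two patients is reported
relative to the *lower*-volume lung.

## Benchtop fixtures

`fixture("benchtop-fig1c-6ft" | "-12ft")` reproduce the validation circuit:
two limbs of 6 ft (1.83 m) or 12 ft (3.66 m) 22 mm tubing, linear test lungs
with selectable compliances (defaults 18 and 35 ml/cmH₂O, the bench-measured
low/medium settings), and filter + one-way-valve accessories at the source
modeled as a directional linear resistance (0.5 + 0.1 cmH₂O·s/L per path,
smoothed over 0.05 cmH₂O to keep the RHS continuous). The per-limb
anti-cross-contamination valve pairs have no one-dimensional flow effect
(a forward and reverse diode in parallel conduct both ways) and are lumped
into the same linear resistance. What the fixtures do *not* emulate:
the physical test lungs' dynamic behaviour. The bench-measured tidal
volumes (352–359 / 566–567 ml at PIP 20 / PEEP 5) exceed C·(PIP−PEEP) for
the statically measured compliances (270 / 525 ml), which a passive linear
RC compartment cannot do; consequently absolute benchtop volumes — and the
~60% tidal-volume differential they imply — are treated as a soft,
documented comparison, not a pass/fail criterion of the simulator. Tests
that pass on these fixtures therefore demonstrate correct circuit physics
for linear lungs, not fidelity to that specific bench hardware.

## Sweep engine and step-size audit

The decision-support table enumerates seven scenario dimensions: PIP, PEEP,
I:E, RR, per-patient compliance, per-patient ETT diameter, and resistor
lumen (with "none"). The default grid is PIP 12–40 step 2 cmH₂O, PEEP 5–20
step 1, I:E ∈ {1:1, 1:1.5, 1:2, 1:3}, RR 10–35 step 5, compliance 10–100
step 5 ml/cmH₂O, ETT 6.0–8.5 step 0.5 mm, resistor {none, 3.0–6.0 step
0.5 mm}, constrained to PIP−PEEP ≥ 5 cmH₂O. These ranges span every
operating point exercised in the validation scenarios; the exact production
grid of the original decision-support table is not public, so this default
is a documented stand-in. The sweep itself is embarrassingly parallel
(joblib) with output order fixed by the lexicographic scenario order, and
failed scenarios are kept as flagged rows.

`step_size_audit` measures, at sampled grid points (default 100 per
dimension, seeded), the relative tidal-volume change 100·|ΔTV|/TV caused by
moving one dimension a single grid step (worst patient; +1 index, −1 at the
top of a list; "none" sits beyond the largest lumen). On the default grid
the audit honestly reports per-dimension maxima far above 5% — e.g. a PIP
step of 2 cmH₂O at driving pressure 5 changes TV by ~40%, a compliance step
10→15 ml/cmH₂O by 50%, and a 3.0→3.5 mm resistor step by ~70% — because
near the quasi-static regime TV ≈ C·(PIP−PEEP) and small resistors are
intentionally high-gain. A grid meeting a 5% criterion in these corners
would need dramatically finer steps (sub-0.25 cmH₂O in PIP, sub-ml/cmH₂O in
compliance, ~0.05 mm in lumen); the audit exists precisely to quantify and
drive that refinement.

## Recommender

`predict_pair` simulates each candidate resistor on the higher-compliance
patient's limb (where it reduces the differential), always including the
no-resistor baseline, and selects by objective: `equalize` (argmin
|TV_A − TV_B|) or `per-patient-targets` (argmin Σ|TV − target|); ties break
toward the larger lumen, counting "none" as the full bore. Both objectives
are provided because the bedside choice between them is clinical. VC mode
is refused without an explicit unsafe opt-in: under volume control the two
patients are coupled (a resistance increase on one limb raises delivered
pressures and volumes to both), so resistor titration under VC is hazardous.
Recommendations are computed by live simulation (~0.1 s per candidate); a
precomputed sweep CSV can serve as a lookup-table backend for parity with an
offline deployment.

## Numerical choices and degenerate inputs

- Flow solves: bracket expansion by doubling then Illinois regula falsi,
  ≤160 iterations, pressure-residual tolerance 1e-9·(1+|Δp|) Pa.
- Mean of endpoint densities in friction terms; the convective term uses
  the endpoint densities as written.
- PIP = PEEP is legal and yields zero tidal volume (used by degenerate
  scenario rows); strictly increasing grids and positive geometry are
  enforced at construction.
- Mass closure at the junction is audited from cumulative-mass states
  integrated alongside the pressures (residual typically ≤1e-10 kg/s,
  asserted ≤1e-8), and it degrades monotonically as the integrator
  tolerance is loosened.
- Problem sizes: tests and the acceptance script run steady-state
  simulations of 5–40 breath cycles at 1 kHz sampling (~0.05–0.3 s each
  after JIT warm-up); the audit samples 100 points per dimension (700
  simulation pairs). The full production-scale table is out of scope; the
  engine streams batches deterministically instead.

## Known limitations

- No alveolar recruitment: raising PEEP at fixed PIP never increases tidal
  volume, by construction.
- No spontaneous breathing, gas exchange, humidification, or tube-wall
  compliance; patients are assumed fully sedated/paralysed.
- Airway resistance is shared between patients in this version.
- The resistor taper geometry is condensed to a 20 mm throat; the physical
  part's continuous taper is not dimensioned, so the throat length is a
  config-exposed estimate.
- Two patient limbs (plus a degenerate single-limb circuit); larger splits
  are a topology extension, not supported in v1.
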