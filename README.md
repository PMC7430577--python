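# splitvent

Lumped-parameter simulation of **split ventilator circuits** — one ventilator
shared by two patients through a Y-split circuit — with inline reduced-lumen
flow resistors, plus the decision-support logic for choosing the resistor
that delivers safe, matched tidal volumes to patients with *different*
pulmonary compliances.

Ventilator splitting is a last-resort strategy for ventilator shortages.
Its central hazard is that two lungs with unequal compliance C receive very
unequal tidal volumes from the same pressure-controlled source: volumes
distribute roughly as C·(PIP−PEEP), so the stiffer lung is hypoventilated
while the more compliant one risks volutrauma. A calibrated flow resistor
placed on the higher-compliance limb re-balances delivery — but choosing its
lumen requires prediction, because delivered volumes respond nonlinearly to
ventilator settings, endotracheal tube (ETT) diameter, compliance and
resistor size. `splitvent` provides that prediction for clinicians,
respiratory-device engineers, and anyone studying multi-patient ventilation.

## Model

The circuit is a compressible gas network: ventilator source → shared 22 mm
tubing → splitter → per patient: (optional resistor) → limb tubing → ETT →
single-compartment lung. Each tubing segment is an ideal-gas node whose
pressure follows the mass balance

    ∂M/∂p · dp_I/dt + ∂M/∂T · dT_I/dt = ṁ_A + ṁ_B,     M = pV/(RT)

with connection flows solved from the quasi-steady momentum balance

    p_A − p_I = (ṁ_A/S)² (1/ρ_I − 1/ρ_A) + Δp_AI

where Δp is Darcy–Weisbach friction (laminar 64/Re, Blasius turbulent,
blended across the transition) plus, for the resistor, contraction and
Borda–Carnot expansion losses of the reduced lumen. Lungs are Kelvin–Voigt
elements, P_aw = V/C + R_aw·dV/dt. The ventilator is a pulse-wave pressure
source between PEEP and PIP (pressure control) or an ideal rectangular flow
source (volume control). Breath cycles are integrated with LSODA until the
per-patient tidal volumes reach a periodic steady state (≥5 cycles). See
`docs/methods.md` for assumptions, parameters and limitations.

## Worked example

Two test lungs of compliance 18 and 35 ml/cmH₂O share one ventilator in
pressure control at PIP 20 / PEEP 5 cmH₂O, RR 20, I:E 1:2, ETT 7.5 mm.
Which resistor on the compliant limb matches the volumes?

```python
from splitvent import PatientProfile, VentilatorSettings, predict_pair

settings = VentilatorSettings(mode="PC", pip=20, peep=5,
                              respiratory_rate=20, ie_ratio=(1, 2))
rec = predict_pair(PatientProfile(compliance=18),
                   PatientProfile(compliance=35),
                   settings, resistor_options=[3.0, 3.5, 4.0, 4.5, 5.0])
print(rec.to_text())
```

```
resistor_mm   tv_A_ml   tv_B_ml  pmax_A_cmH2O  pmax_B_cmH2O  objective_score  selected
       none     269.9     514.8          20.0          20.0            244.9     False
          3     269.9     199.7          20.0          12.5             70.2     False
        3.5     269.9     260.4          20.0          14.1              9.4      True
          4     269.9     318.3          20.0          15.7             48.5     False
        4.5     269.9     369.3          20.0          17.1             99.5     False
          5     269.9     411.3          20.0          18.2            141.4     False
```

Unrestricted, the compliant lung receives 515 ml against 270 ml — a 91%
differential. The 3.5 mm lumen nearly equalizes delivery (260 vs 270 ml)
while 3.0 mm overshoots and *inverts* the imbalance; the selected row
minimises |TV_A − TV_B|. Note `tv_A` barely moves across rows: under
pressure control the resistor only affects its own limb, the safety property
that makes titration possible (under volume control the patients couple,
which is why VC recommendations require an explicit unsafe flag). `pmax_B`
shows the resistor limb never reaching the set PIP.

The same is available from the shell:

```bash
splitvent recommend --compliance-a 18 --compliance-b 35 --pip 20 --peep 5 \
    --rr 20 --ie 1:2 --resistor 3.0,3.5,4.0,4.5,5.0
splitvent simulate --fixture benchtop-fig1c-6ft --out run/   # waveforms + summary
splitvent sweep --grid grid.yaml --out table.csv             # scenario table
splitvent audit --samples 20                                  # grid-resolution audit
```

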