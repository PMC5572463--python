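# lateralwall

A closed-loop ion-transport model of the cochlear lateral wall. The
package simulates the endocochlear potential (EP), the intrastrial
potential (ISP), compartment K⁺ concentrations, and the circulation
current of a 10-µm cochlear slice, under normal conditions and during
blockade of the syncytial Na⁺,K⁺-ATPases, together with the steady-state
parameter calibration and blocking-rate estimation procedures.

## Model in one paragraph

Six membrane domains are connected in series through six compartments:

```
perilymph --SB--> syncytium --SA--> intrastrial space --MB-->
marginal cell --MA--> endolymph --HA--> hair cell --HB--> perilymph
```

Each membrane carries Ohmic conductances and/or transporters
(Na⁺,K⁺-ATPase at fixed 3:2 stoichiometry, MET conductance on the
hair-cell apical surface).  The hair-cell apical membrane is treated as
purely resistive, so the loop (circulation) current always equals the
MET current; membrane potentials obey `dv/dt = (±I_Cir − I_M)/C` and
compartment concentrations obey `d[X]/dt = (I_in − I_out)/(VF)`.  EP and
ISP are derived quantities (`EP = v_SB − v_SA + v_MB − v_MA`,
`ISP = v_SB − v_SA`), and `v_HA = −EP + v_HB` closes the loop.
Sign conventions are documented in `src/lateralwall/model_core.py`.

Element magnitudes are not free parameters: the calibration layer solves
them so that the measured normal-condition operating point is an exact
fixed point of the ODEs (the syncytial basolateral triple from its
flux-balance equations including local Na⁺ recycling; the K⁺-selective
conductances and marginal-cell elements from per-ion flux balance).

## CLI

```sh
lateralwall calibrate  --out calibration_report.json
lateralwall steady     --out steady_out/
lateralwall block      --kappa 0.46 --t-end 2400 --out block_out/
lateralwall scan-kappa --from 0.30 --to 0.60 --step 0.01 --out scan_out/
lateralwall decompose  --kappa 0.46 --out decompose_out/
```

All commands default to the bundled reference fixture
(`src/lateralwall/data/reference.yaml`); pass `--config my.yaml` to
override.  `kappa` follows the published blocking-rate notation: the
pump activity is scaled **to** κ×normal (κ = 0.46 means 46% of normal
activity remains; smaller κ is a stronger block).

Reports are written as `report.csv` / `report.txt` plus trace CSVs with
fixed columns: `time_s, v_SB, v_SA, v_MB, v_MA, v_HB, v_HA, EP, ISP,
I_Cir, conc_<compartment>_<ion>...`.  Every report records the config
hash and solver settings, and identical configs reproduce bit-identical
outputs.

## Configuration

One YAML file describes the whole model: physical constants,
compartments (volume, per-ion concentrations, which ions are dynamic),
membranes (capacitance, initial potential, cell count, elements), the
calibration closure parameters, and the default scenario.  Element
magnitudes may be `null`, in which case they are solved by the
calibration layer; every value carries a provenance note.  The schema is
strict: unknown keys, negative volumes, or unknown ions are rejected
with messages naming the offending field.

## Fidelity notes

The published supplementary parameter table and per-element kinetic
equations are not bundled.  The fixture therefore reconstructs the model
from the main-text equations, the measured operating point, printed
morphometry, and documented fallbacks (Michaelis–Menten pump kinetics
operating Na⁺-saturated, a fixed Na⁺-conductance/leak ratio pinned by
the published 2.5–2.8 nA pump-current band, literature values for
unmeasured concentrations).  With this parameterisation the normal
steady state, blocked EP, circulation-current plateau, pump-current
band, ISP-overlay consistency, and all structural invariants reproduce
the published results; the blocked v_SB/ISP and some fitted time
constants deviate (see `tests/test_acceptance.py`, criteria 2–4, which
are intentionally left failing rather than loosened — cation bookkeeping
makes the printed blocked v_SB unreachable without additional
supplementary-only structure such as osmotic volume dynamics).
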