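"""Published reference values used by the validation experiments.

All numbers are transcribed once, here, from the source publication for
the model (steady-state comparison table, results text, and supplementary
scan), so tests and reports never hard-code them in multiple places.
Potentials are mV, concentrations mM, currents nA, time constants s.
"""

#: simulated steady state under normal conditions (600-s settle)
SIMULATED_NORMAL = {
    "EP": 72.7,
    "v_SB": 9.6,
    "K_SY": 98.3,
    "ISP": 81.2,
    "K_IS": 6.1,
}

#: simulated values 40 min after blocking the syncytial pumps (kappa=0.46)
SIMULATED_BLOCKED = {
    "EP": 9.6,
    "v_SB": -3.0,
    "K_SY": 10.4,
    "ISP": 15.1,
    "K_IS": 4.7,
}

#: in-vivo measurements (mean, SD) 40 min into 10 uM ouabain perfusion —
#: the acceptance ranges for the blocking-rate scan
EXPERIMENT_OUABAIN = {
    "EP": (5.8, 6.2),
    "v_SB": (-6.2, 2.6),
    "K_SY": (14.3, 1.5),
    "ISP": (10.6, 4.4),
    "K_IS": (4.2, 1.4),
}

#: in-vivo control measurements (mean, SD) before the perfusion
EXPERIMENT_CONTROL = {
    "EP": (83.2, 3.6),
    "v_SB": (9.9, 1.2),
    "K_SY": (101.7, 15.1),
    "ISP": (68.7, 4.6),
    "K_IS": (8.6, 2.5),
}

#: fitted exponential time constants of the blockade response
TAU_S = {
    "v_SB": 240.0,
    "K_SY": 288.2,
    "EP": 454.4,
    "ISP": 453.6,
    "K_IS": 454.1,
    "I_Cir": 467.9,
    "I_K_leak_SB": 89.2,
    "I_Na_conductance_SB": 169.6,
}

#: circulation-current plateau reached ~30 min into the blockade
I_CIR_PLATEAU_NA = -1.9

#: outward pump Na+ current stays in this band throughout the blockade
PUMP_NA_BAND_NA = (2.5, 2.8)

#: blocking rate selected by the scan against the measured ranges
SELECTED_KAPPA = 0.46

#: morphometry worked example (printed means)
MORPHOMETRY = {
    "area_stria_um2": 12107.1,
    "area_ligament_um2": 74353.8,
    "cellular_fraction_stria": 0.916,
    "cellular_fraction_ligament": 0.423,
    "n_strial_cells": 56,
    "n_fibrocytes": 168,
}

#: declared tolerances (solver/fit-window sensitivity)
TOL_POTENTIAL_MV = 0.5
TOL_CONC_MM = 0.5
TOL_TAU_REL = 0.10
TOL_PLATEAU_NA = 0.1

LOCATIONS = {
    "EP": "steady-state comparison table",
    "v_SB": "steady-state comparison table",
    "K_SY": "steady-state comparison table",
    "ISP": "steady-state comparison table",
    "K_IS": "steady-state comparison table",
    "v_MB_minus_v_MA": "model-description text (<10 mV)",
    "I_Cir_plateau": "results text, current-decomposition figure",
    "tau": "results text",
    "selected_kappa": "blocking-rate scan (supplementary figure)",
}
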