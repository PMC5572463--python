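"""Steady-state parameter calibration.

Under-constrained element magnitudes are recovered from a measured
normal-condition operating point:

* the syncytial basolateral (SB) triple — pump activity, Na+ conductance,
  leak conductance — from the SB flux-balance equations (total current
  equals the oriented loop current; K+ uptake balances the apical K+
  efflux; net Na+ current is zero, i.e. local Na+ recycling);
* the purely K+-selective conductances (SA, MA, HB) and the marginal-cell
  basolateral elements, by requiring every membrane current to equal the
  oriented loop current and every compartment to be in per-ion flux
  balance at the measured state.

The three SB balance equations are rank-deficient (the total-current
equation is the sum of the per-ion ones once the loop closure holds), so
a fixed Na+-conductance : leak-conductance ratio closes the system; the
ratio is a configuration input flagged as a fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    LOOP_SIGN,
    CONDUCTANCE_KINDS,
    ElementKind,
    Ion,
    PhysicalConstants,
    System,
    SystemState,
    nernst_potential,
)

__all__ = [
    "CalibrationError",
    "BlockingRateError",
    "MeasuredSteadyState",
    "SBParameters",
    "solve_sb_parameters",
    "BlockingScan",
    "KappaScanResult",
    "estimate_blocking_rate",
    "MorphometryInput",
    "MorphometryResult",
    "morphometry_to_cell_counts",
]


class CalibrationError(RuntimeError):
    pass


class BlockingRateError(RuntimeError):
    pass


@dataclass
class MeasuredSteadyState:
    """Measured potentials/concentrations plus the loop current.

    ``loop_current`` follows the package convention (MET current in the
    hair-cell apical outward-positive convention; negative at rest).
    """

    potentials: dict[str, float]
    concentrations: dict[str, dict[Ion, float]]
    loop_current: float

    def __post_init__(self) -> None:
        for c, ions in self.concentrations.items():
            for ion, v in ions.items():
                if v <= 0:
                    raise CalibrationError(
                        f"measured [{ion}] in {c} must be positive, got {v}"
                    )


@dataclass
class SBParameters:
    """Solved SB magnitudes (totals for the whole fibrocyte population)."""

    pump_net_current_na: float   # net pump current at the measured state
    g_na_us: float               # Na+ conductance, uS
    g_leak_us: float             # leak conductance (K+ + Na+ partial), uS
    residuals: tuple[float, float, float] = (0.0, 0.0, 0.0)


def solve_sb_parameters(
    measured: MeasuredSteadyState,
    na_to_leak_ratio: float,
    leak_weights: tuple[float, float] = (0.5, 0.5),
    constants: PhysicalConstants = PhysicalConstants(),
    perilymph: str = "perilymph_ST",
    syncytium: str = "syncytium",
) -> SBParameters:
    """Solve the SB balance equations for (pump, G_Na, G_leak).

    The equations are linear in the three magnitudes at the fixed
    measured state.  Because the total-current balance is the exact sum
    of the per-ion balances, the literal 3x3 system is singular; the
    ``na_to_leak_ratio`` constraint replaces the redundant equation and
    all three balance residuals are verified afterwards (raising
    :class:`CalibrationError` if the measured data are inconsistent).
    """
    v = measured.potentials["SB"]
    out = measured.concentrations[perilymph]
    inn = measured.concentrations[syncytium]
    j = measured.loop_current
    w_k, w_na = leak_weights
    if not math.isclose(w_k + w_na, 1.0, rel_tol=1e-9):
        raise CalibrationError("leak per-ion weights must sum to 1")
    d_k = v - nernst_potential(Ion.K, out[Ion.K], inn[Ion.K], constants,
                               where="SB leak (K)")
    d_na = v - nernst_potential(Ion.Na, out[Ion.Na], inn[Ion.Na], constants,
                                where="SB Na conductance")
    # unknowns x = (q, G_Na, g_leak); rows: K balance, Na balance, ratio
    a = np.array([
        [-2.0, 0.0, w_k * d_k],
        [3.0, d_na, w_na * d_na],
        [0.0, 1.0, -na_to_leak_ratio],
    ])
    b = np.array([j, 0.0, 0.0])
    try:
        q, g_na, g_leak = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise CalibrationError(f"singular SB calibration system: {exc}") from exc
    res_total = q + g_na * d_na + g_leak * (w_k * d_k + w_na * d_na) - j
    res_k = -2.0 * q + g_leak * w_k * d_k - j
    res_na = 3.0 * q + g_na * d_na + g_leak * w_na * d_na
    scale = max(abs(j), 1e-12)
    for name, r in (("total", res_total), ("K", res_k), ("Na", res_na)):
        if abs(r) / scale > 1e-8:
            raise CalibrationError(
                f"inconsistent SB balance ({name}): residuals "
                f"total={res_total:.3e}, K={res_k:.3e}, Na={res_na:.3e} nA"
            )
    for name, val in (("pump activity", q), ("Na conductance", g_na),
                      ("leak conductance", g_leak)):
        if val < 0:
            raise CalibrationError(
                f"negative solved SB parameter: {name} = {val:.4g}"
            )
    return SBParameters(
        pump_net_current_na=float(q),
        g_na_us=float(g_na),
        g_leak_us=float(g_leak),
        residuals=(float(res_total), float(res_k), float(res_na)),
    )


# ---------------------------------------------------------------------------
# blocking-rate estimation
# ---------------------------------------------------------------------------

@dataclass
class BlockingScan:
    """Scan configuration for the pump blocking rate kappa.

    ``acceptance_ranges`` maps observable name -> (mean, sd); a simulated
    value qualifies when it lies within mean +/- sd.  All observables are
    evaluated at the same post-block time for every kappa.
    """

    kappa_grid: Sequence[float]
    acceptance_ranges: Mapping[str, tuple[float, float]]
    t_post_block_s: float = 2400.0

    def __post_init__(self) -> None:
        grid = list(self.kappa_grid)
        if any(not 0.0 <= k <= 1.0 for k in grid):
            raise ValueError("kappa grid values must lie in [0, 1]")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("kappa grid must be sorted ascending")


@dataclass
class KappaScanResult:
    selected_kappa: float
    table: pd.DataFrame          # one row per kappa, one column per observable
    qualified: list[float]


def estimate_blocking_rate(
    scan: BlockingScan,
    runner: Callable[[float], Mapping[str, float]],
    fallback_to_nearest: bool = False,
) -> KappaScanResult:
    """Pick the blocking rate whose simulated observables fit the data.

    ``runner(kappa)`` must return the simulated observables at the scan's
    post-block time.  Among the kappas whose observables all fall within
    the acceptance ranges, the one minimising the summed squared z-scores
    against the range midpoints is returned (ties broken by grid order,
    so the result is deterministic).  If no kappa qualifies a
    :class:`BlockingRateError` lists the nearest miss per observable,
    unless ``fallback_to_nearest`` is set, in which case the global
    z-score minimiser is selected and ``qualified`` is left empty.
    """
    names = list(scan.acceptance_ranges)
    rows = []
    for kappa in scan.kappa_grid:
        obs = runner(kappa)
        missing = [n for n in names if n not in obs]
        if missing:
            raise BlockingRateError(
                f"runner output lacks observables {missing} at kappa={kappa}"
            )
        rows.append({"kappa": kappa, **{n: float(obs[n]) for n in names}})
    table = pd.DataFrame(rows)

    def zsq(row) -> float:
        total = 0.0
        for n in names:
            mean, sd = scan.acceptance_ranges[n]
            if not math.isfinite(sd) or sd == 0:
                continue
            total += ((row[n] - mean) / sd) ** 2
        return total

    qualified = []
    for _, row in table.iterrows():
        ok = True
        for n in names:
            mean, sd = scan.acceptance_ranges[n]
            if not (mean - sd <= row[n] <= mean + sd):
                ok = False
                break
        if ok:
            qualified.append(float(row["kappa"]))
    if not qualified:
        if fallback_to_nearest:
            scores = [zsq(row) for _, row in table.iterrows()]
            selected = float(table["kappa"][int(np.argmin(scores))])
            return KappaScanResult(
                selected_kappa=selected, table=table, qualified=[]
            )
        misses = []
        for n in names:
            mean, sd = scan.acceptance_ranges[n]
            gaps = np.abs(table[n] - mean) - sd
            i = int(np.argmin(gaps))
            misses.append(
                f"{n}: nearest kappa={table['kappa'][i]:.2f} misses "
                f"[{mean - sd:.2f}, {mean + sd:.2f}] by {max(gaps[i], 0):.3f}"
            )
        raise BlockingRateError(
            "no kappa satisfies all acceptance ranges; " + "; ".join(misses)
        )
    scores = [
        zsq(table[table["kappa"] == k].iloc[0]) for k in qualified
    ]
    selected = qualified[int(np.argmin(scores))]
    return KappaScanResult(
        selected_kappa=selected, table=table, qualified=qualified
    )


# ---------------------------------------------------------------------------
# morphometry
# ---------------------------------------------------------------------------

# ---------------------------------------------------------------------------
# whole-system calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibratedModel:
    """A fully wired system whose configured state is an exact fixed point."""

    system: System
    state: SystemState
    report: dict


def _single_ion_conductance(
    mid: str, el_name: str, ion: Ion, j: float,
    v: float, e: float, n_cells: int,
) -> float:
    """Per-cell conductance pinning I = LOOP_SIGN * I_Cir at the state."""
    target = LOOP_SIGN[mid] * j
    drive = v - e
    if abs(drive) < 1e-12:
        raise CalibrationError(
            f"{mid}.{el_name}: zero driving force, conductance unresolvable"
        )
    g_us = target / drive
    if g_us <= 0:
        raise CalibrationError(
            f"{mid}.{el_name}: solved conductance is non-positive "
            f"({g_us:.4g} uS); check the measured state"
        )
    return g_us / (1e-3 * n_cells)


def _pump_saturation(na_in: float, k_out: float, params: dict) -> float:
    km_na = params.get("km_na_mm", 10.0)
    km_k = params.get("km_k_mm", 1.5)
    return (na_in / (na_in + km_na)) ** 3 * (k_out / (k_out + km_k)) ** 2


def calibrate_system(config) -> CalibratedModel:
    """Resolve every ``null`` element magnitude from the measured state.

    Implements the steady-state calibration: the loop current is fixed by
    the MET conductance at the configured potentials/concentrations, the
    SB triple comes from :func:`solve_sb_parameters`, the K+-selective
    conductances (SA, MA, HB) are pinned by the loop current, and the
    marginal-cell basolateral pump/NSC pair is pinned by the per-ion flux
    balance of the marginal cell.  The returned state has derivative
    residuals at round-off level by construction; this is verified.
    """
    from .io_cli import build_compartments  # schema lives with the CLI layer
    from .model_core import TransportElement, Membrane, met_current
    from . import engine

    consts = PhysicalConstants(
        F=config.constants.faraday_c_per_mol,
        R=config.constants.gas_r_j_per_mol_k,
        T=config.constants.temperature_k,
    )
    compartments = build_compartments(config)
    free = {m: config.membranes[m].potential_mv
            for m in ("SB", "SA", "MB", "MA", "HB")}
    conc0 = {cid: dict(c.conc) for cid, c in compartments.items()}
    state = SystemState.from_free(free, conc0)
    adjustments: list[str] = []

    v_ha_cfg = config.membranes["HA"].potential_mv
    if abs(v_ha_cfg - state.potentials["HA"]) > 1e-6:
        raise CalibrationError(
            f"configured v_HA={v_ha_cfg} violates the loop closure "
            f"v_HA = -EP + v_HB = {state.potentials['HA']:.6f}"
        )

    if config.calibration.set_marginal_cl_to_equilibrium:
        cl_eq = (
            state.conc("intrastrial_space", Ion.Cl)
            * math.exp(state.potentials["MB"] / consts.rt_f_mv)
        )
        old = state.concentrations["marginal_cell"][Ion.Cl]
        state.concentrations["marginal_cell"][Ion.Cl] = cl_eq
        compartments["marginal_cell"].conc[Ion.Cl] = cl_eq
        if abs(cl_eq - old) > 1e-9:
            adjustments.append(
                f"marginal_cell [Cl] set to ClC equilibrium: "
                f"{old:.4g} -> {cl_eq:.6g} mM"
            )

    # loop current from the (fixed) MET conductance
    ha_cfg = config.membranes["HA"]
    met_names = [n for n, e in ha_cfg.elements.items()
                 if e.kind is ElementKind.MET_CHANNEL]
    if len(met_names) != 1 or ha_cfg.elements[met_names[0]].magnitude_per_cell is None:
        raise CalibrationError(
            "HA must carry exactly one MET element with a fixed magnitude"
        )
    g_met_total = (
        ha_cfg.elements[met_names[0]].magnitude_per_cell * ha_cfg.n_cells
    )
    j = met_current(
        g_met_total,
        state.potentials["HA"],
        state.conc("endolymph", Ion.K),
        state.conc("hair_cell", Ion.K),
        consts,
    )

    measured = MeasuredSteadyState(
        potentials=dict(state.potentials),
        concentrations={c: dict(v) for c, v in state.concentrations.items()},
        loop_current=j,
    )
    w_k = config.calibration.sb_leak_weight_k
    sb = solve_sb_parameters(
        measured,
        na_to_leak_ratio=config.calibration.sb_na_to_leak_ratio,
        leak_weights=(w_k, 1.0 - w_k),
        constants=consts,
    )
    p_mb = config.calibration.mb_pump_net_current_na

    solved: dict[str, dict] = {}
    fallbacks: list[str] = [
        "pump kinetics: saturable Michaelis-Menten fallback "
        "(km_na_mm, km_k_mm element parameters)",
        f"SB closure: Na-conductance/leak ratio fixed at "
        f"{config.calibration.sb_na_to_leak_ratio} (balance equations are "
        f"rank-deficient), leak K weight {w_k}",
        f"MB closure: pump net current at the measured state fixed at "
        f"{p_mb} nA",
    ]

    membranes: dict[str, Membrane] = {}
    for mid, mcfg in config.membranes.items():
        v = state.potentials[mid]
        inn = state.concentrations[mcfg.inner]
        out = state.concentrations[mcfg.outer]
        elements = []
        for name, ecfg in mcfg.elements.items():
            ions = {Ion(i): wgt for i, wgt in ecfg.ions.items()}
            mag = ecfg.magnitude_per_cell
            if mag is None:
                if mid == "SB":
                    if ecfg.kind is ElementKind.NAK_ATPASE:
                        sat = _pump_saturation(
                            inn[Ion.Na], out[Ion.K], ecfg.params
                        )
                        mag = sb.pump_net_current_na / (sat * mcfg.n_cells)
                        ions = {Ion.Na: 3.0, Ion.K: -2.0}
                    elif ecfg.kind is ElementKind.LEAK_CONDUCTANCE:
                        mag = sb.g_leak_us / (1e-3 * mcfg.n_cells)
                        ions = {Ion.K: w_k, Ion.Na: 1.0 - w_k}
                    elif ions == {Ion.Na: 1.0}:
                        mag = sb.g_na_us / (1e-3 * mcfg.n_cells)
                    else:
                        raise CalibrationError(
                            f"cannot calibrate SB element {name!r}"
                        )
                elif mid == "MB" and ecfg.kind is ElementKind.NAK_ATPASE:
                    sat = _pump_saturation(inn[Ion.Na], out[Ion.K], ecfg.params)
                    mag = p_mb / (sat * mcfg.n_cells)
                    ions = {Ion.Na: 3.0, Ion.K: -2.0}
                elif mid == "MB" and ecfg.kind is ElementKind.NSC_CONDUCTANCE:
                    e_na = nernst_potential(
                        Ion.Na, out[Ion.Na], inn[Ion.Na], consts, where="MB NSC"
                    )
                    e_k = nernst_potential(
                        Ion.K, out[Ion.K], inn[Ion.K], consts, where="MB NSC"
                    )
                    g_na = -3.0 * p_mb / (v - e_na)
                    g_k = (j + 2.0 * p_mb) / (v - e_k)
                    if g_na <= 0 or g_k < 0:
                        raise CalibrationError(
                            f"MB NSC calibration gave non-physical partial "
                            f"conductances g_Na={g_na:.4g}, g_K={g_k:.4g} uS"
                        )
                    g_tot = g_na + g_k
                    ions = {Ion.Na: g_na / g_tot, Ion.K: g_k / g_tot}
                    mag = g_tot / (1e-3 * mcfg.n_cells)
                elif (ecfg.kind in CONDUCTANCE_KINDS and len(ions) == 1):
                    (ion,) = ions
                    e = nernst_potential(
                        ion, out[ion], inn[ion], consts, where=f"{mid}.{name}"
                    )
                    mag = _single_ion_conductance(
                        mid, name, ion, j, v, e, mcfg.n_cells
                    )
                else:
                    raise CalibrationError(
                        f"no calibration rule for {mid}.{name} ({ecfg.kind})"
                    )
                solved[f"{mid}.{name}"] = {
                    "magnitude_per_cell": float(mag),
                    "total": float(mag * mcfg.n_cells),
                    "ion_weights": {str(i): float(wgt)
                                    for i, wgt in ions.items()},
                    "provenance": ecfg.provenance or "calibrated",
                }
            elements.append(TransportElement(
                name=name, kind=ecfg.kind, ions=ions,
                magnitude=float(mag), scale=mcfg.n_cells,
                params=dict(ecfg.params),
            ))
        membranes[mid] = Membrane(
            id=mid, inner=mcfg.inner, outer=mcfg.outer,
            capacitance_nf=mcfg.capacitance_nf, elements=elements,
        )

    system = System(
        constants=consts, compartments=compartments, membranes=membranes
    )
    rhs = engine.assemble_rhs(system)
    y0 = engine.pack_state(system, state)
    dy = rhs(0.0, y0)
    residual = float(
        np.max(np.abs(dy) / np.maximum(np.abs(y0), 1.0))
    )
    if residual > 1e-8:
        raise CalibrationError(
            f"calibrated state is not a fixed point (max scaled residual "
            f"{residual:.3e}); per-equation residuals: {dy.tolist()}"
        )
    report = {
        "loop_current_na": float(j),
        "sb_solution": {
            "pump_net_current_na": sb.pump_net_current_na,
            "g_na_us": sb.g_na_us,
            "g_leak_us": sb.g_leak_us,
            "balance_residuals_na": list(sb.residuals),
        },
        "solved_elements": solved,
        "residual_max_scaled": residual,
        "fallbacks": fallbacks,
        "adjustments": adjustments,
    }
    return CalibratedModel(system=system, state=state, report=report)


@dataclass
class MorphometryInput:
    """Printed tissue areas and cellular-area fractions of a cross-section."""

    area_stria_um2: float
    area_ligament_um2: float
    cellular_fraction_stria: float
    cellular_fraction_ligament: float
    n_strial_cells: int

    def __post_init__(self) -> None:
        if self.area_stria_um2 <= 0 or self.area_ligament_um2 <= 0:
            raise ValueError("tissue areas must be positive")
        for name in ("cellular_fraction_stria", "cellular_fraction_ligament"):
            f = getattr(self, name)
            if not 0.0 < f <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {f}")


@dataclass
class MorphometryResult:
    tissue_ratio: float      # raw ligament:stria cellular-area ratio
    rounded_ratio: int
    n_fibrocytes: int


def morphometry_to_cell_counts(m: MorphometryInput) -> MorphometryResult:
    """Ligament:stria cellular-area ratio and the implied fibrocyte count.

    The raw ratio is rounded to the nearest integer before multiplying by
    the strial cell count, matching the 1:n bookkeeping used to size the
    model's fibrocyte population.
    """
    cellular_stria = m.area_stria_um2 * m.cellular_fraction_stria
    cellular_ligament = m.area_ligament_um2 * m.cellular_fraction_ligament
    if cellular_stria == 0 or cellular_ligament == 0:
        raise ValueError("cellular area must be nonzero")
    ratio = cellular_ligament / cellular_stria
    rounded = int(round(ratio))
    return MorphometryResult(
        tissue_ratio=ratio,
        rounded_ratio=rounded,
        n_fibrocytes=m.n_strial_cells * rounded,
    )
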