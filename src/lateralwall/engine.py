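"""ODE assembly, integration, steady states, and time-constant fitting.

The dynamical state is ``[v_SB, v_SA, v_MB, v_MA, v_HB]`` followed by the
dynamic compartment concentrations; ``v_HA`` is slaved to the loop-closure
identity ``v_HA = -EP + v_HB`` (the hair-cell apical membrane is treated
as purely resistive, so the loop current equals the MET current at all
times).  Membrane charging obeys

    dv/dt = (LOOP_SIGN * I_Cir - I_M) / C

and compartment concentrations obey  d[X]/dt = (I_X,in - I_X,out)/(V F),
with inflow/outflow read off the flux breakdown of the membranes bounding
the compartment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit, least_squares

from .model_core import (
    COMPARTMENT_SHORT,
    LOOP_SIGN,
    VALENCE,
    FluxBreakdown,
    Ion,
    System,
    SystemState,
)

__all__ = [
    "Perturbation",
    "TimeSeries",
    "TimeConstantFit",
    "IntegrationError",
    "SteadyStateError",
    "DegenerateFitError",
    "DYNAMIC_POTENTIALS",
    "assemble_rhs",
    "integrate",
    "find_steady_state",
    "fit_time_constant",
    "flux_decomposition",
    "isp_consistency_check",
]

DYNAMIC_POTENTIALS = ("SB", "SA", "MB", "MA", "HB")

#: default stiff-solver settings (capacitive charging is ~ms, concentration
#: dynamics are ~minutes); recorded in every report for reproducibility
SOLVER_SETTINGS = {"method": "BDF", "rtol": 1e-8, "atol": 1e-9}

MV_PER_VOLT = 1e3     # nA / nF = V/s
NA_TO_MMOL = 1e-6     # nA / (F * L) = 1e-6 mM/s


class IntegrationError(RuntimeError):
    pass


class SteadyStateError(RuntimeError):
    pass


class DegenerateFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class Perturbation:
    """A step change in one element's activity (e.g. pump blockade).

    ``factor`` multiplies the element magnitude between ``onset`` and
    ``offset`` (open-ended when ``offset`` is None).  A blocking rate
    kappa corresponds to ``factor = 1 - kappa``.
    """

    membrane: str
    element: str
    factor: float
    onset: float = 0.0
    offset: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.factor <= 1.0:
            raise ValueError(f"factor must be in [0, 1], got {self.factor}")
        if self.offset is not None and not self.onset < self.offset:
            raise ValueError("onset must precede offset")

    def active(self, t: float) -> bool:
        return t >= self.onset and (self.offset is None or t < self.offset)


def _factors_at(
    perturbations: Sequence[Perturbation], t: float
) -> dict[tuple[str, str], float]:
    factors: dict[tuple[str, str], float] = {}
    for p in perturbations:
        if p.active(t):
            key = (p.membrane, p.element)
            factors[key] = factors.get(key, 1.0) * p.factor
    return factors


# ---------------------------------------------------------------------------
# state-vector packing
# ---------------------------------------------------------------------------

def pack_state(system: System, state: SystemState) -> np.ndarray:
    idx = system.dynamic_concentration_index()
    y = [state.potentials[m] for m in DYNAMIC_POTENTIALS]
    y += [state.concentrations[c][ion] for c, ion in idx]
    return np.asarray(y, dtype=float)


def unpack_state(system: System, y: np.ndarray, t: float = 0.0) -> SystemState:
    idx = system.dynamic_concentration_index()
    conc = {c.id: dict(c.conc) for c in system.compartments.values()}
    for k, (cid, ion) in enumerate(idx):
        conc[cid][ion] = float(y[len(DYNAMIC_POTENTIALS) + k])
    pot = {m: float(y[i]) for i, m in enumerate(DYNAMIC_POTENTIALS)}
    state = SystemState.from_free(pot, conc, time=t)
    return state


def assemble_rhs(
    system: System,
    perturbations: Sequence[Perturbation] = (),
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build d(state)/dt for the closed-loop circuit.

    Raises :class:`IntegrationError` (with a state dump) if a clearly
    negative concentration is encountered; tiny negative solver probes
    are tolerated by flooring log arguments far below physiological
    values.
    """
    idx = system.dynamic_concentration_index()
    caps = {m: system.membranes[m].capacitance_nf for m in DYNAMIC_POTENTIALS}
    f_const = system.constants.F
    # membranes bounding each compartment, with outward-positive bookkeeping
    inner_of: dict[str, list[str]] = {c: [] for c in system.compartments}
    outer_of: dict[str, list[str]] = {c: [] for c in system.compartments}
    for mid, mem in system.membranes.items():
        inner_of[mem.inner].append(mid)
        outer_of[mem.outer].append(mid)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        concs = y[len(DYNAMIC_POTENTIALS):]
        if np.any(concs < -1e-6):
            bad = int(np.argmin(concs))
            cid, ion = idx[bad]
            raise IntegrationError(
                f"negative [{ion}] in {cid} at t={t:.3f}s "
                f"({concs[bad]:.3e} mM); state={y.tolist()}"
            )
        yw = y.copy()
        yw[len(DYNAMIC_POTENTIALS):] = np.maximum(concs, 1e-9)
        state = unpack_state(system, yw, t)
        factors = _factors_at(perturbations, t)
        fb = system.breakdown(state, factors)
        j = fb.loop_current
        dy = np.empty_like(y)
        for i, m in enumerate(DYNAMIC_POTENTIALS):
            dy[i] = MV_PER_VOLT * (
                LOOP_SIGN[m] * j - fb.per_membrane_total[m]
            ) / caps[m]
        for k, (cid, ion) in enumerate(idx):
            flow = 0.0  # nA of ion entering the compartment
            for mid in outer_of[cid]:
                flow += fb.net_per_ion.get((mid, ion), 0.0)
            for mid in inner_of[cid]:
                flow -= fb.net_per_ion.get((mid, ion), 0.0)
            vol = system.compartments[cid].volume_l
            dy[len(DYNAMIC_POTENTIALS) + k] = (
                NA_TO_MMOL * flow / (VALENCE[ion] * f_const * vol)
            )
        return dy

    return rhs


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class TimeSeries:
    """A sampled trajectory plus everything needed to re-derive fluxes."""

    system: System
    times: np.ndarray
    values: np.ndarray                      # (n_samples, n_state)
    perturbations: tuple[Perturbation, ...] = ()

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def state_at(self, i: int) -> SystemState:
        return unpack_state(self.system, self.values[i], float(self.times[i]))

    def states(self) -> Iterable[SystemState]:
        for i in range(len(self)):
            yield self.state_at(i)

    def observable(self, name: str) -> np.ndarray:
        """Named trace: EP, ISP, I_Cir, v_<mem>, or <Ion>_<short compartment>.

        Examples: ``"EP"``, ``"v_SB"``, ``"K_SY"``, ``"Na_IS"``.
        """
        if name in ("EP", "ISP"):
            return np.array(
                [getattr(s, name.lower()) for s in self.states()]
            )
        if name == "I_Cir":
            return np.array([
                self.system.loop_current(
                    self.state_at(i),
                    _factors_at(self.perturbations, float(self.times[i])),
                )
                for i in range(len(self))
            ])
        if name.startswith("v_"):
            mem = name[2:]
            return np.array([s.potentials[mem] for s in self.states()])
        ion_name, _, short = name.partition("_")
        ion = Ion(ion_name)
        by_short = {v: k for k, v in COMPARTMENT_SHORT.items()}
        cid = by_short[short]
        return np.array([s.conc(cid, ion) for s in self.states()])

    def element_current(
        self, membrane: str, element: str, ion: Ion
    ) -> np.ndarray:
        """Trace of one element's per-ion current (nA) along the series."""
        out = np.empty(len(self))
        for i in range(len(self)):
            fb = self.system.breakdown(
                self.state_at(i),
                _factors_at(self.perturbations, float(self.times[i])),
            )
            out[i] = fb.entries.get((membrane, element, Ion(ion)), 0.0)
        return out

    def final_state(self) -> SystemState:
        return self.state_at(len(self) - 1)

    def to_frame(self) -> pd.DataFrame:
        """Fixed-schema CSV table (see README for the column contract)."""
        data: dict[str, np.ndarray] = {"time_s": self.times}
        for m in ("SB", "SA", "MB", "MA", "HB", "HA"):
            data[f"v_{m}"] = self.observable(f"v_{m}")
        for name in ("EP", "ISP", "I_Cir"):
            data[name] = self.observable(name)
        for cid, ion in self.system.dynamic_concentration_index():
            data[f"conc_{cid}_{ion}"] = self.observable(
                f"{ion}_{COMPARTMENT_SHORT[cid]}"
            )
        return pd.DataFrame(data)


def integrate(
    system: System,
    state0: SystemState,
    t_end: float,
    perturbations: Sequence[Perturbation] = (),
    dt_out: float = 1.0,
    **solver_overrides,
) -> TimeSeries:
    """Integrate the circuit for ``t_end`` seconds (output every dt_out).

    The integration is split at perturbation switch times so the stiff
    solver never steps across an activity discontinuity.  Deterministic
    for fixed inputs and solver settings.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    settings = {**SOLVER_SETTINGS, **solver_overrides}
    rhs = assemble_rhs(system, perturbations)
    switches = sorted({
        t for p in perturbations
        for t in (p.onset, p.offset)
        if t is not None and 0.0 < t < t_end
    })
    bounds = [0.0, *switches, t_end]
    t_eval = np.round(np.arange(0.0, t_end + dt_out / 2, dt_out), 9)
    times: list[float] = []
    rows: list[np.ndarray] = []
    y = pack_state(system, state0)
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg_eval = t_eval[(t_eval >= a) & (t_eval <= b)]
        if len(seg_eval) == 0 or seg_eval[0] > a:
            seg_eval = np.concatenate([[a], seg_eval])
        # evaluate flux factors just inside the segment: shift the RHS
        # clock so a step at the segment start is already active
        eps = 1e-9
        sol = solve_ivp(
            lambda t, yy: rhs(min(t + eps, b), yy),
            (a, b), y, t_eval=seg_eval, **settings,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed in [{a}, {b}] s: {sol.message}; "
                f"last valid t={sol.t[-1] if len(sol.t) else a}"
            )
        y = sol.y[:, -1]
        for k, t in enumerate(sol.t):
            if times and math.isclose(t, times[-1], abs_tol=1e-9):
                continue
            times.append(float(t))
            rows.append(sol.y[:, k])
    return TimeSeries(
        system=system,
        times=np.asarray(times),
        values=np.asarray(rows),
        perturbations=tuple(perturbations),
    )


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------

def _scaled_residual(y: np.ndarray, dy: np.ndarray) -> float:
    return float(np.max(np.abs(dy) / np.maximum(np.abs(y), 1.0)))


def find_steady_state(
    system: System,
    guess: SystemState,
    perturbations: Sequence[Perturbation] = (),
    tol: float = 1e-8,
    settle_s: float = 600.0,
) -> SystemState:
    """Root-find the fixed point nearest ``guess``.

    Ion conservation leaves a null space (total moles of each ion are
    free), so a Levenberg-Marquardt least-squares solve is used; the
    pre-settle integration fixes the conserved totals and the polish
    stays on that manifold.  Raises :class:`SteadyStateError` with the
    residual profile on failure.
    """
    rhs = assemble_rhs(system, perturbations)
    # settle first: pins the conserved ion totals and gives LM a good start
    if settle_s > 0:
        series = integrate(system, guess, settle_s, perturbations)
        y0 = series.values[-1]
    else:
        y0 = pack_state(system, guess)
    res = least_squares(
        lambda y: rhs(1e12, y), y0, method="lm", xtol=1e-15, ftol=1e-15,
    )
    dy = rhs(1e12, res.x)
    if _scaled_residual(res.x, dy) > tol:
        raise SteadyStateError(
            "steady state not reached; scaled residual profile: "
            f"{(dy / np.maximum(np.abs(res.x), 1.0)).tolist()}"
        )
    return unpack_state(system, res.x, 0.0)


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------

@dataclass
class TimeConstantFit:
    """Single-exponential fit ``A exp(-(t-t0)/tau) + B`` of one trace."""

    tau: float
    asymptote: float
    amplitude: float
    rmse: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def fit_time_constant(
    series: TimeSeries,
    observable: str | np.ndarray,
    window: tuple[float, float],
) -> TimeConstantFit:
    """Least-squares exponential fit of an observable over ``window``.

    ``observable`` may be a trace name (see :meth:`TimeSeries.observable`)
    or a precomputed array aligned with ``series.times``.  The rmse is
    always reported so departures from single-exponential behaviour stay
    visible; a constant trace raises :class:`DegenerateFitError`.
    """
    t0, t1 = window
    mask = (series.times >= t0) & (series.times <= t1)
    if int(mask.sum()) < 10:
        raise ValueError("window must contain at least 10 samples")
    t = series.times[mask] - t0
    y = (series.observable(observable) if isinstance(observable, str)
         else np.asarray(observable))[mask]
    if float(np.ptp(y)) < 1e-12:
        raise DegenerateFitError(
            f"observable is constant over window {window}"
        )

    def model(tt, a, tau, b):
        return a * np.exp(-tt / tau) + b

    b0 = float(y[-1])
    a0 = float(y[0] - y[-1])
    # crude 1/e-crossing estimate for tau
    target = b0 + a0 / math.e
    crossings = np.nonzero(np.diff(np.sign(y - target)))[0]
    tau0 = float(t[crossings[0]]) if len(crossings) else float(t[-1] / 5)
    tau0 = max(tau0, float(t[1] - t[0]))
    popt, _ = curve_fit(
        model, t, y, p0=(a0, tau0, b0),
        bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    a, tau, b = map(float, popt)
    rmse = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
    return TimeConstantFit(
        tau=tau, asymptote=b, amplitude=a, rmse=rmse, window=(t0, t1)
    )


def flux_decomposition(series: TimeSeries) -> pd.DataFrame:
    """Per-time, per-membrane, per-element, per-ion current table.

    Long format: time_s, membrane, element, ion, current_na.  Net per-ion
    rows carry element="net", and the loop current is repeated per time
    with membrane="loop", element="I_Cir".
    """
    records: list[dict] = []
    for i in range(len(series)):
        t = float(series.times[i])
        state = series.state_at(i)
        fb = series.system.breakdown(state, _factors_at(series.perturbations, t))
        for (mid, el, ion), cur in fb.entries.items():
            records.append({
                "time_s": t, "membrane": mid, "element": el,
                "ion": str(ion), "current_na": cur,
            })
        for (mid, ion), cur in fb.net_per_ion.items():
            records.append({
                "time_s": t, "membrane": mid, "element": "net",
                "ion": str(ion), "current_na": cur,
            })
        records.append({
            "time_s": t, "membrane": "loop", "element": "I_Cir",
            "ion": "", "current_na": fb.loop_current,
        })
    return pd.DataFrame.from_records(records)


@dataclass
class ISPConsistency:
    """Direct ISP vs the K+-equilibrium approximation across SA."""

    frame: pd.DataFrame
    max_abs_mv: float
    rms_mv: float


def isp_consistency_check(series: TimeSeries) -> ISPConsistency:
    """Compare ISP = v_SB - v_SA with v_SB - (RT/F) ln([K]_IS/[K]_SY).

    The difference trace is always reported, never discarded; it vanishes
    exactly in the limit of an ideal K+-selective syncytial apical
    surface carrying zero loop current.
    """
    rt_f = series.system.constants.rt_f_mv
    v_sb = series.observable("v_SB")
    isp = series.observable("ISP")
    k_is = series.observable("K_IS")
    k_sy = series.observable("K_SY")
    approx = v_sb - rt_f * np.log(k_is / k_sy)
    diff = isp - approx
    frame = pd.DataFrame({
        "time_s": series.times,
        "isp_direct_mv": isp,
        "isp_approx_mv": approx,
        "difference_mv": diff,
    })
    return ISPConsistency(
        frame=frame,
        max_abs_mv=float(np.max(np.abs(diff))),
        rms_mv=float(np.sqrt(np.mean(diff ** 2))),
    )
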