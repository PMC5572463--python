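"""Domain types, physical constants, and per-element flux laws.

The cochlear lateral wall is modelled as a closed electrical loop of six
membrane domains connected in series through six ionic compartments:

    perilymph --SB--> syncytium --SA--> intrastrial space --MB-->
    marginal cell --MA--> endolymph --HA--> hair cell --HB--> perilymph

Every membrane potential ``v`` is intracellular minus adjacent
extracellular, and every membrane current is positive when positive charge
flows from the intracellular side to the designated extracellular side.

Sign convention for the loop current
------------------------------------
The loop (circulation) current ``I_Cir`` is defined as the summed current
through the hair-cell mechanoelectrical-transduction (MET) conductance in
the hair-cell apical membrane's own outward-positive convention.  At rest
K+ flows from endolymph *into* the hair cells, so ``I_Cir`` is negative
(about -3 nA for the three hair cells of a 10-um slice).  The oriented
loop current seen by membrane ``m`` in its own outward-positive convention
is ``LOOP_SIGN[m] * I_Cir``:

    ======== ===== ==============================================
    membrane sign  loop current at rest (outward-positive)
    ======== ===== ==============================================
    SB        +1   inward  (perilymph -> syncytium)
    SA        -1   outward (syncytium -> intrastrial space)
    MB        +1   inward  (intrastrial space -> marginal cell)
    MA        -1   outward (marginal cell -> endolymph)
    HA        +1   inward  (endolymph -> hair cell)  [= I_Cir itself]
    HB        -1   outward (hair cell -> perilymph)
    ======== ===== ==============================================

With this orientation the steady state satisfies
``I_M(m) == LOOP_SIGN[m] * I_Cir`` on every membrane, and the syncytial
basolateral balance reads ``I_NaKATP,SB + I_NaConductance,SB + I_Leak,SB
= I_Cir`` (which equals the conventional form ``... = -I_Cir`` when the
loop current is instead oriented positive in the circulation direction).

Units: mV, mM, nA, nF, seconds, liters.  Per-cell conductances are nS and
per-cell transporter magnitudes are nA; totals are obtained by multiplying
with the cell count of the membrane (``TransportElement.scale``).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

__all__ = [
    "PhysicalConstants",
    "Ion",
    "VALENCE",
    "ElementKind",
    "Compartment",
    "TransportElement",
    "Membrane",
    "SystemState",
    "FluxBreakdown",
    "System",
    "LOOP_SIGN",
    "MEMBRANE_ORDER",
    "COMPARTMENT_SHORT",
    "ConcentrationError",
    "ConfigurationError",
    "nernst_potential",
    "ohmic_channel_current",
    "met_current",
    "nak_atpase_current",
    "transporter_current",
    "membrane_total_current",
]

NS_TO_US = 1e-3  # nS * mV -> pA; keep currents in nA


class ConcentrationError(ValueError):
    """A non-positive concentration was used where a log is required."""


class ConfigurationError(ValueError):
    """The model wiring (kinds, ions, parameters) is inconsistent."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants; temperature defaults to body temperature."""

    F: float = 96485.33212  # C/mol
    R: float = 8.314462618  # J/(mol K)
    T: float = 310.15       # K

    @property
    def rt_f_mv(self) -> float:
        """Thermal voltage RT/F in millivolts (~26.7 mV at 310.15 K)."""
        return 1e3 * self.R * self.T / self.F


class Ion(str, enum.Enum):
    K = "K"
    Na = "Na"
    Cl = "Cl"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


VALENCE: dict[Ion, int] = {Ion.K: +1, Ion.Na: +1, Ion.Cl: -1}


class ElementKind(str, enum.Enum):
    OHMIC_CHANNEL = "ohmic_channel"
    MET_CHANNEL = "met_channel"
    NAK_ATPASE = "nak_atpase"
    LEAK_CONDUCTANCE = "leak_conductance"
    NSC_CONDUCTANCE = "nsc_conductance"
    NA_TRANSPORTER = "na_transporter"
    CL_TRANSPORTER = "cl_transporter"
    CLC_CHANNEL = "clc_channel"


#: element kinds whose flux law is ohmic with per-ion partial conductances
CONDUCTANCE_KINDS = {
    ElementKind.OHMIC_CHANNEL,
    ElementKind.LEAK_CONDUCTANCE,
    ElementKind.NSC_CONDUCTANCE,
    ElementKind.CLC_CHANNEL,
}

MEMBRANE_ORDER = ("SB", "SA", "MB", "MA", "HA", "HB")

#: orientation of the loop current in each membrane's outward-positive
#: convention (see module docstring)
LOOP_SIGN: dict[str, int] = {
    "SB": +1, "SA": -1, "MB": +1, "MA": -1, "HA": +1, "HB": -1,
}

COMPARTMENT_SHORT = {
    "perilymph_ST": "PL",
    "perilymph_SV": "PV",
    "endolymph": "EL",
    "intrastrial_space": "IS",
    "syncytium": "SY",
    "marginal_cell": "MC",
    "hair_cell": "HC",
}


@dataclass
class Compartment:
    """An intra- or extracellular space with a volume and ion contents.

    Ions listed in ``dynamic`` evolve by the compartment concentration
    ODE; the others are held constant (no transport path exists for them).
    """

    id: str
    volume_l: float
    conc: dict[Ion, float]
    dynamic: frozenset[Ion] = frozenset()

    def __post_init__(self) -> None:
        if self.volume_l <= 0:
            raise ConfigurationError(
                f"compartment {self.id!r}: volume must be positive, "
                f"got {self.volume_l}"
            )
        for ion, c in self.conc.items():
            if c < 0:
                raise ConfigurationError(
                    f"compartment {self.id!r}: [{ion}] must be >= 0, got {c}"
                )


@dataclass
class TransportElement:
    """A channel or transporter attached to one membrane domain.

    ``magnitude`` is per cell: nS for conductance kinds, maximal net-cycle
    current (nA) for the Na+,K+-ATPase, maximal transport current (nA) for
    carrier kinds.  ``ions`` holds per-ion weights: fractional partial
    conductances for conductance kinds (must sum to 1), and the fixed
    stoichiometry (+3 Na / -2 K) for the pump.  ``scale`` is the cell
    count of the membrane the element sits on.
    """

    name: str
    kind: ElementKind
    ions: dict[Ion, float]
    magnitude: float
    scale: int = 1
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ConfigurationError(
                f"element {self.name!r}: magnitude must be >= 0, "
                f"got {self.magnitude}"
            )
        if self.kind in CONDUCTANCE_KINDS and self.ions:
            total = sum(self.ions.values())
            if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-12):
                raise ConfigurationError(
                    f"element {self.name!r}: per-ion conductance weights "
                    f"must sum to 1, got {total}"
                )


@dataclass
class Membrane:
    """One of the six membrane domains, with its attached elements."""

    id: str
    inner: str
    outer: str
    capacitance_nf: float
    elements: list[TransportElement] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.capacitance_nf <= 0:
            raise ConfigurationError(
                f"membrane {self.id}: capacitance must be positive"
            )


@dataclass
class SystemState:
    """Full instantaneous state: six potentials plus all concentrations.

    ``EP`` and ``ISP`` are always derived (never stored), and ``v_HA`` is
    slaved to the loop-closure identity ``v_HA = -EP + v_HB``; use
    :meth:`from_free` to build a state that satisfies it by construction.
    """

    potentials: dict[str, float]           # membrane id -> mV
    concentrations: dict[str, dict[Ion, float]]  # compartment -> ion -> mM
    time: float = 0.0

    @classmethod
    def from_free(
        cls,
        potentials: Mapping[str, float],
        concentrations: Mapping[str, Mapping[Ion, float]],
        time: float = 0.0,
    ) -> "SystemState":
        """Build a state from the five free potentials (HA is derived)."""
        pot = {m: float(potentials[m]) for m in ("SB", "SA", "MB", "MA", "HB")}
        ep = pot["SB"] - pot["SA"] + pot["MB"] - pot["MA"]
        pot["HA"] = -ep + pot["HB"]
        conc = {c: {Ion(i): float(v) for i, v in ions.items()}
                for c, ions in concentrations.items()}
        return cls(potentials=pot, concentrations=conc, time=time)

    @property
    def ep(self) -> float:
        p = self.potentials
        return p["SB"] - p["SA"] + p["MB"] - p["MA"]

    @property
    def isp(self) -> float:
        p = self.potentials
        return p["SB"] - p["SA"]

    def conc(self, compartment: str, ion: Ion) -> float:
        return self.concentrations[compartment][ion]

    def copy(self) -> "SystemState":
        return SystemState(
            potentials=dict(self.potentials),
            concentrations={c: dict(v) for c, v in self.concentrations.items()},
            time=self.time,
        )


@dataclass
class FluxBreakdown:
    """Per-membrane, per-element, per-ion current table (nA)."""

    entries: dict[tuple[str, str, Ion], float]
    per_membrane_total: dict[str, float]
    net_per_ion: dict[tuple[str, Ion], float]
    loop_current: float

    def membrane_entries(self, membrane: str) -> dict[tuple[str, Ion], float]:
        return {
            (el, ion): i
            for (m, el, ion), i in self.entries.items()
            if m == membrane
        }


# ---------------------------------------------------------------------------
# flux laws
# ---------------------------------------------------------------------------

def nernst_potential(
    ion: Ion,
    conc_out: float,
    conc_in: float,
    constants: PhysicalConstants = PhysicalConstants(),
    *,
    where: str = "",
) -> float:
    """Equilibrium potential (mV) of ``ion``: (RT/zF) ln(out/in)."""
    if conc_out <= 0 or conc_in <= 0:
        ctx = f" at {where}" if where else ""
        raise ConcentrationError(
            f"non-positive [{ion}]{ctx}: out={conc_out} mM, in={conc_in} mM"
        )
    z = VALENCE[Ion(ion)]
    return constants.rt_f_mv / z * math.log(conc_out / conc_in)


def ohmic_channel_current(
    element: TransportElement,
    v: float,
    e_rev: Mapping[Ion, float] | float,
) -> dict[Ion, float]:
    """Ohmic current ``I = G (v - E_X)`` per permeant ion, in nA.

    ``e_rev`` maps each permeant ion to its reversal potential; a scalar
    is broadcast (valid for single-ion channels).  The per-cell
    conductance is split by the element's per-ion weights and multiplied
    by the cell count.
    """
    if element.kind not in CONDUCTANCE_KINDS:
        raise ConfigurationError(
            f"element {element.name!r} of kind {element.kind} is not ohmic"
        )
    g_total_us = element.magnitude * element.scale * NS_TO_US
    out: dict[Ion, float] = {}
    for ion, w in element.ions.items():
        e = e_rev if isinstance(e_rev, (int, float)) else e_rev[ion]
        out[Ion(ion)] = g_total_us * w * (v - e)
    return out


def met_current(
    g_met_ns: float,
    v_ha: float,
    conc_el_k: float,
    conc_hc_k: float,
    constants: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Summed MET current (nA) for the hair cells of a slice.

    ``g_met_ns`` is the total (already cell-count-scaled) MET conductance.
    By the closed-loop construction this current is the circulation
    current; it is negative at rest (K+ enters the hair cells).
    """
    e_k = nernst_potential(Ion.K, conc_el_k, conc_hc_k, constants,
                           where="hair-cell apical (MET)")
    return g_met_ns * NS_TO_US * (v_ha - e_k)


def nak_atpase_current(
    element: TransportElement,
    v: float,  # noqa: ARG001 - kept in the signature for the flux contract
    na_in: float,
    k_out: float,
    block_fraction: float = 0.0,
) -> dict[Ion, float]:
    """Na+,K+-ATPase per-ion currents (nA) at fixed 3:2 stoichiometry.

    Saturable fallback kinetics: the cycle rate is Michaelis-Menten in
    intracellular [Na+] (Hill 3) and extracellular [K+] (Hill 2); the
    published per-transporter-type formulation is not bundled, so the
    half-activation constants are exposed as element parameters
    ``km_na_mm`` / ``km_k_mm``.  The net current per cycle is one
    elementary charge outward: I_Na = +3u, I_K = -2u with u >= 0.
    """
    if not 0.0 <= block_fraction <= 1.0:
        raise ValueError(f"block_fraction must be in [0, 1], got {block_fraction}")
    if na_in < 0 or k_out < 0:
        raise ConcentrationError(
            f"pump {element.name!r}: negative substrate concentration "
            f"(na_in={na_in}, k_out={k_out})"
        )
    km_na = element.params.get("km_na_mm", 10.0)
    km_k = element.params.get("km_k_mm", 1.5)
    sat = (na_in / (na_in + km_na)) ** 3 * (k_out / (k_out + km_k)) ** 2
    u = element.magnitude * element.scale * (1.0 - block_fraction) * sat
    return {Ion.Na: 3.0 * u, Ion.K: -2.0 * u}


def transporter_current(
    element: TransportElement,
    v: float,
    conc_in: Mapping[Ion, float],
    conc_out: Mapping[Ion, float],
    constants: PhysicalConstants = PhysicalConstants(),
    block_fraction: float = 0.0,
) -> dict[Ion, float]:
    """Per-ion currents (nA) for any supported element kind.

    Conductance kinds are ohmic against each ion's own Nernst potential;
    the pump uses :func:`nak_atpase_current`; carrier kinds
    (``na_transporter`` / ``cl_transporter``) extrude their substrate with
    Michaelis-Menten saturation on the intracellular concentration
    (parameter ``km_mm``).  Currents follow the outward-positive membrane
    convention, so Cl- extrusion is a negative Cl- current.
    """
    kind = element.kind
    if kind in CONDUCTANCE_KINDS:
        e_rev = {
            ion: nernst_potential(ion, conc_out[ion], conc_in[ion], constants,
                                  where=element.name)
            for ion in element.ions
        }
        cur = ohmic_channel_current(element, v, e_rev)
    elif kind is ElementKind.NAK_ATPASE:
        cur = nak_atpase_current(
            element, v, conc_in[Ion.Na], conc_out[Ion.K], block_fraction
        )
    elif kind is ElementKind.MET_CHANNEL:
        i = met_current(
            element.magnitude * element.scale, v,
            conc_out[Ion.K], conc_in[Ion.K], constants,
        )
        cur = {Ion.K: i}
    elif kind is ElementKind.NA_TRANSPORTER:
        km = element.params.get("km_mm", 10.0)
        na = conc_in[Ion.Na]
        rate = element.magnitude * element.scale * na / (na + km)
        cur = {Ion.Na: rate * (1.0 - block_fraction)}
    elif kind is ElementKind.CL_TRANSPORTER:
        km = element.params.get("km_mm", 25.0)
        cl = conc_in[Ion.Cl]
        rate = element.magnitude * element.scale * cl / (cl + km)
        # Cl- moved outward carries negative charge outward -> negative I
        cur = {Ion.Cl: -rate * (1.0 - block_fraction)}
    else:  # pragma: no cover - enum is exhaustive
        raise ConfigurationError(f"unknown element kind {kind!r}")
    if block_fraction and kind in CONDUCTANCE_KINDS:
        cur = {ion: i * (1.0 - block_fraction) for ion, i in cur.items()}
    return cur


def membrane_total_current(
    membrane: Membrane,
    state: SystemState,
    constants: PhysicalConstants = PhysicalConstants(),
    factors: Mapping[tuple[str, str], float] | None = None,
) -> tuple[float, dict[tuple[str, Ion], float]]:
    """Total membrane current I_M and its per-element per-ion entries.

    ``factors`` optionally scales element activity (key ``(membrane id,
    element name)``); a factor f is applied as ``block_fraction = 1 - f``.
    Returns ``(I_M, {(element, ion): nA})`` with I_M equal to the sum of
    all entries.
    """
    v = state.potentials[membrane.id]
    conc_in = state.concentrations[membrane.inner]
    conc_out = state.concentrations[membrane.outer]
    entries: dict[tuple[str, Ion], float] = {}
    total = 0.0
    for el in membrane.elements:
        f = 1.0
        if factors:
            f = factors.get((membrane.id, el.name), 1.0)
        cur = transporter_current(
            el, v, conc_in, conc_out, constants, block_fraction=1.0 - f
        )
        for ion, i in cur.items():
            entries[(el.name, ion)] = entries.get((el.name, ion), 0.0) + i
            total += i
    return total, entries


# ---------------------------------------------------------------------------
# assembled system
# ---------------------------------------------------------------------------

@dataclass
class System:
    """The wired lateral-wall circuit: compartments + membranes + constants.

    The loop current is read from the membrane named by ``loop_source``
    (the hair-cell apical surface, which carries only the MET
    conductance and no capacitive term).
    """

    constants: PhysicalConstants
    compartments: dict[str, Compartment]
    membranes: dict[str, Membrane]
    loop_source: str = "HA"

    def __post_init__(self) -> None:
        for m in self.membranes.values():
            for side in (m.inner, m.outer):
                if side not in self.compartments:
                    raise ConfigurationError(
                        f"membrane {m.id}: unknown compartment {side!r}"
                    )
        if self.loop_source not in self.membranes:
            raise ConfigurationError(
                f"loop source membrane {self.loop_source!r} not defined"
            )

    def reference_state(self, potentials: Mapping[str, float]) -> SystemState:
        """State at the configured initial concentrations and potentials."""
        conc = {c.id: dict(c.conc) for c in self.compartments.values()}
        return SystemState.from_free(potentials, conc)

    def breakdown(
        self,
        state: SystemState,
        factors: Mapping[tuple[str, str], float] | None = None,
    ) -> FluxBreakdown:
        """Evaluate every element flux at ``state`` (pure function)."""
        entries: dict[tuple[str, str, Ion], float] = {}
        totals: dict[str, float] = {}
        net: dict[tuple[str, Ion], float] = {}
        for mid, mem in self.membranes.items():
            total, mem_entries = membrane_total_current(
                mem, state, self.constants, factors
            )
            totals[mid] = total
            for (el, ion), i in mem_entries.items():
                entries[(mid, el, ion)] = i
                net[(mid, ion)] = net.get((mid, ion), 0.0) + i
        return FluxBreakdown(
            entries=entries,
            per_membrane_total=totals,
            net_per_ion=net,
            loop_current=totals[self.loop_source],
        )

    def loop_current(
        self,
        state: SystemState,
        factors: Mapping[tuple[str, str], float] | None = None,
    ) -> float:
        total, _ = membrane_total_current(
            self.membranes[self.loop_source], state, self.constants, factors
        )
        return total

    def with_scaled_element(
        self, membrane: str, element: str, factor: float
    ) -> "System":
        """Return a copy with one element magnitude permanently scaled."""
        membranes = {}
        for mid, mem in self.membranes.items():
            els = []
            for el in mem.elements:
                if mid == membrane and el.name == element:
                    el = replace(el, magnitude=el.magnitude * factor)
                els.append(el)
            membranes[mid] = replace(mem, elements=els)
        return System(
            constants=self.constants,
            compartments=self.compartments,
            membranes=membranes,
            loop_source=self.loop_source,
        )

    def dynamic_concentration_index(self) -> list[tuple[str, Ion]]:
        """Stable ordering of the dynamic (compartment, ion) pairs."""
        order = list(COMPARTMENT_SHORT)
        idx: list[tuple[str, Ion]] = []
        for cid in sorted(self.compartments, key=order.index):
            comp = self.compartments[cid]
            for ion in (Ion.K, Ion.Na, Ion.Cl):
                if ion in comp.dynamic:
                    idx.append((cid, ion))
        return idx
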