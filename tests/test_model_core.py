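import math

import pytest
from hypothesis import given, strategies as st

from lateralwall.model_core import (
    LOOP_SIGN,
    ConcentrationError,
    ConfigurationError,
    ElementKind,
    Ion,
    PhysicalConstants,
    SystemState,
    TransportElement,
    Membrane,
    membrane_total_current,
    met_current,
    nak_atpase_current,
    nernst_potential,
    ohmic_channel_current,
    transporter_current,
)

CONST = PhysicalConstants()

conc = st.floats(min_value=0.05, max_value=500.0,
                 allow_nan=False, allow_infinity=False)


def make_channel(kind=ElementKind.OHMIC_CHANNEL, ions=None, g=1.0, scale=1):
    return TransportElement(
        name="ch", kind=kind, ions=ions or {Ion.K: 1.0},
        magnitude=g, scale=scale,
    )


def make_pump(mag=1.0, scale=1, **params):
    return TransportElement(
        name="pump", kind=ElementKind.NAK_ATPASE,
        ions={Ion.Na: 3.0, Ion.K: -2.0}, magnitude=mag, scale=scale,
        params=params,
    )


class TestNernst:
    def test_equal_concentrations_give_zero(self):
        assert nernst_potential(Ion.K, 10.0, 10.0, CONST) == 0.0

    def test_thermal_voltage_at_body_temperature(self):
        assert CONST.rt_f_mv == pytest.approx(26.726659112967557, rel=1e-12)

    def test_reference_gradient(self):
        # closed-form oracle: (RT/F) ln(6.1/98.3) at 310.15 K
        e = nernst_potential(Ion.K, 6.1, 98.3, CONST)
        assert e == pytest.approx(-74.29303661071084, rel=1e-12)

    @given(out=conc, inn=conc)
    def test_antisymmetric_under_swap(self, out, inn):
        a = nernst_potential(Ion.K, out, inn, CONST)
        b = nernst_potential(Ion.K, inn, out, CONST)
        assert a == pytest.approx(-b, abs=1e-9)

    @given(out=conc, inn=conc)
    def test_chloride_flips_sign(self, out, inn):
        ek = nernst_potential(Ion.K, out, inn, CONST)
        ecl = nernst_potential(Ion.Cl, out, inn, CONST)
        assert ecl == pytest.approx(-ek, abs=1e-9)

    def test_nonpositive_concentration_is_domain_error(self):
        with pytest.raises(ConcentrationError, match="syncytium"):
            nernst_potential(Ion.K, 0.0, 98.3, CONST, where="syncytium")


class TestOhmic:
    def test_zero_at_reversal(self):
        cur = ohmic_channel_current(make_channel(), v=-74.3, e_rev=-74.3)
        assert cur[Ion.K] == 0.0

    def test_unit_arithmetic(self):
        # 1 nS at 10 mV driving force -> 0.01 nA
        cur = ohmic_channel_current(make_channel(g=1.0), v=10.0, e_rev=0.0)
        assert cur[Ion.K] == pytest.approx(0.01, rel=1e-12)

    @given(g=st.floats(0.01, 100), drive=st.floats(-150, 150))
    def test_linear_in_conductance(self, g, drive):
        a = ohmic_channel_current(make_channel(g=g), drive, 0.0)[Ion.K]
        b = ohmic_channel_current(make_channel(g=2 * g), drive, 0.0)[Ion.K]
        assert b == pytest.approx(2 * a, rel=1e-9, abs=1e-15)

    def test_cell_count_scaling(self):
        a = ohmic_channel_current(make_channel(scale=1), 10.0, 0.0)[Ion.K]
        b = ohmic_channel_current(make_channel(scale=40), 10.0, 0.0)[Ion.K]
        assert b == pytest.approx(40 * a)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ConfigurationError, match="sum to 1"):
            make_channel(ions={Ion.K: 0.5, Ion.Na: 0.2})

    def test_pump_is_not_ohmic(self):
        with pytest.raises(ConfigurationError, match="not ohmic"):
            ohmic_channel_current(make_pump(), 0.0, 0.0)


class TestMET:
    def test_zero_driving_force(self):
        e = nernst_potential(Ion.K, 150.0, 140.0, CONST)
        assert met_current(24.0, e, 150.0, 140.0, CONST) == pytest.approx(0.0)

    def test_resting_magnitude_about_one_na_per_hair_cell(self):
        # fixture operating point: ~1 nA per cell, ~3 nA per slice, inward
        i = met_current(3 * 8.0, -122.7, 150.0, 140.0, CONST)
        assert -3.2 < i < -2.7
        assert i / 3 == pytest.approx(-1.0, abs=0.1)

    def test_linear_in_conductance(self):
        i1 = met_current(24.0, -122.7, 150.0, 140.0, CONST)
        i2 = met_current(12.0, -122.7, 150.0, 140.0, CONST)
        assert i2 == pytest.approx(i1 / 2)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ConcentrationError):
            met_current(24.0, -122.7, -1.0, 140.0, CONST)


class TestPump:
    def test_full_block_gives_zero(self):
        cur = nak_atpase_current(make_pump(), 0.0, 10.0, 5.0, block_fraction=1.0)
        assert cur[Ion.Na] == 0.0 and cur[Ion.K] == 0.0

    @given(na=conc, k=conc, block=st.floats(0.0, 0.999))
    def test_stoichiometry_three_to_two(self, na, k, block):
        cur = nak_atpase_current(make_pump(), 0.0, na, k, block)
        assert cur[Ion.Na] >= 0.0 and cur[Ion.K] <= 0.0
        if cur[Ion.K] != 0.0:
            assert abs(cur[Ion.Na]) / abs(cur[Ion.K]) == pytest.approx(1.5)

    def test_net_charge_one_per_cycle(self):
        cur = nak_atpase_current(make_pump(), 0.0, 10.0, 5.0)
        net = cur[Ion.Na] + cur[Ion.K]
        assert net == pytest.approx(cur[Ion.Na] / 3.0)

    @given(na=st.floats(0.5, 200), k=st.floats(0.5, 200))
    def test_monotone_in_substrates(self, na, k):
        base = nak_atpase_current(make_pump(), 0.0, na, k)[Ion.Na]
        more_na = nak_atpase_current(make_pump(), 0.0, na * 1.5, k)[Ion.Na]
        more_k = nak_atpase_current(make_pump(), 0.0, na, k * 1.5)[Ion.Na]
        assert more_na >= base and more_k >= base

    def test_block_fraction_out_of_range(self):
        with pytest.raises(ValueError, match="block_fraction"):
            nak_atpase_current(make_pump(), 0.0, 10.0, 5.0, block_fraction=1.5)


class TestTransporterDispatch:
    IN = {Ion.K: 98.3, Ion.Na: 10.0, Ion.Cl: 30.0}
    OUT = {Ion.K: 5.0, Ion.Na: 145.0, Ion.Cl: 120.0}

    @pytest.mark.parametrize("kind", list(ElementKind))
    def test_zero_magnitude_gives_zero_everywhere(self, kind):
        ions = {Ion.Cl: 1.0} if kind in (
            ElementKind.CLC_CHANNEL, ElementKind.CL_TRANSPORTER
        ) else {Ion.K: 1.0}
        if kind is ElementKind.NAK_ATPASE:
            ions = {Ion.Na: 3.0, Ion.K: -2.0}
        el = TransportElement(name="x", kind=kind, ions=ions, magnitude=0.0)
        cur = transporter_current(el, -20.0, self.IN, self.OUT, CONST)
        assert all(i == 0.0 for i in cur.values())

    def test_k_channel_reverses_at_nernst(self):
        el = make_channel()
        e = nernst_potential(Ion.K, self.OUT[Ion.K], self.IN[Ion.K], CONST)
        below = transporter_current(el, e - 5, self.IN, self.OUT, CONST)[Ion.K]
        above = transporter_current(el, e + 5, self.IN, self.OUT, CONST)[Ion.K]
        assert below < 0 < above

    def test_per_ion_components_sum_to_net(self):
        el = TransportElement(
            name="leak", kind=ElementKind.LEAK_CONDUCTANCE,
            ions={Ion.K: 0.5, Ion.Na: 0.5}, magnitude=2.0, scale=10,
        )
        cur = transporter_current(el, 9.6, self.IN, self.OUT, CONST)
        assert set(cur) == {Ion.K, Ion.Na}
        # components computed against their own reversal potentials
        ek = nernst_potential(Ion.K, 5.0, 98.3, CONST)
        ena = nernst_potential(Ion.Na, 145.0, 10.0, CONST)
        assert cur[Ion.K] == pytest.approx(2.0 * 10 * 0.5e-3 * (9.6 - ek))
        assert cur[Ion.Na] == pytest.approx(2.0 * 10 * 0.5e-3 * (9.6 - ena))

    def test_cl_transporter_extrusion_is_negative_current(self):
        el = TransportElement(
            name="clt", kind=ElementKind.CL_TRANSPORTER,
            ions={Ion.Cl: 1.0}, magnitude=1.0,
        )
        cur = transporter_current(el, 0.0, self.IN, self.OUT, CONST)
        assert cur[Ion.Cl] < 0


class TestStateIdentities:
    POTS = st.floats(-150, 150, allow_nan=False)

    @given(sb=POTS, sa=POTS, mb=POTS, ma=POTS, hb=POTS)
    def test_ep_isp_identities(self, sb, sa, mb, ma, hb):
        state = SystemState.from_free(
            {"SB": sb, "SA": sa, "MB": mb, "MA": ma, "HB": hb},
            {"x": {Ion.K: 1.0}},
        )
        assert state.ep == pytest.approx(sb - sa + mb - ma)
        assert state.isp == pytest.approx(sb - sa)
        assert state.ep - state.isp == pytest.approx(mb - ma)
        # loop closure: v_HA is slaved to -EP + v_HB
        assert state.potentials["HA"] == pytest.approx(-state.ep + hb)


class TestMembraneTotals:
    def test_membrane_with_no_elements(self, model):
        mem = Membrane(id="SB", inner="syncytium", outer="perilymph_ST",
                       capacitance_nf=1.0, elements=[])
        total, entries = membrane_total_current(mem, model.state)
        assert total == 0.0 and entries == {}

    def test_sb_composition_at_steady_state(self, model):
        fb = model.system.breakdown(model.state)
        parts = fb.membrane_entries("SB")
        by_el = {}
        for (el, ion), i in parts.items():
            by_el[el] = by_el.get(el, 0.0) + i
        assert set(by_el) == {"nak_atpase", "na_conductance", "leak"}
        assert sum(by_el.values()) == pytest.approx(
            fb.per_membrane_total["SB"], rel=1e-9
        )
        # SB total equals the oriented loop current (steady state)
        assert fb.per_membrane_total["SB"] == pytest.approx(
            LOOP_SIGN["SB"] * fb.loop_current, rel=1e-9
        )

    def test_breakdown_bookkeeping(self, model):
        fb = model.system.breakdown(model.state)
        for mid in model.system.membranes:
            total = sum(i for (m, _, _), i in fb.entries.items() if m == mid)
            assert total == pytest.approx(
                fb.per_membrane_total[mid], rel=1e-9, abs=1e-12
            )
            for ion in Ion:
                net = sum(
                    i for (m, _, io), i in fb.entries.items()
                    if m == mid and io == ion
                )
                assert net == pytest.approx(
                    fb.net_per_ion.get((mid, ion), 0.0), rel=1e-9, abs=1e-12
                )
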