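"""The NMDA-gated LTP rule: gate, charge accumulation, forgetting, memory."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipposim.neuron_core import CellParams, CellState, Compartment, SynapseClass
from hipposim.plasticity import (
    CAMT_MV,
    LTPState,
    PlasticityParams,
    effective_weight,
    ltp_gate,
    memory_value,
    plasticity_step,
    update_charge,
)

PARAMS = PlasticityParams()


class TestGate:
    @pytest.mark.parametrize(
        "s_k, expected",
        [(-67.0, True), (-68.0, False), (-80.0, False), (-67.999, True)],
    )
    def test_strict_threshold_at_camt(self, s_k, expected):
        assert ltp_gate(s_k, CAMT_MV) is expected


class TestUpdateCharge:
    def test_rest_level_adds_nothing(self):
        assert update_charge(0.0, M_head=-80.0, gated=True, params=PARAMS) == 0.0

    def test_increment_for_12mv_depolarization(self):
        # 12 mV = 0.012 V -> exp(0.12) - 1
        c = update_charge(0.0, M_head=-68.0, gated=True, params=PARAMS)
        assert c == pytest.approx(math.expm1(0.12), rel=1e-12)
        assert c == pytest.approx(0.12750, abs=5e-6)

    def test_forgetting_step_subtracts_fq(self):
        assert update_charge(5.0, -80.0, gated=False, params=PARAMS, decay_due=True) == 4.0

    def test_forgetting_only_when_charge_exceeds_fq(self):
        assert update_charge(0.8, -80.0, False, PARAMS, decay_due=True) == 0.8

    def test_charge_never_negative(self):
        p = PlasticityParams(FQ=1.0)
        c = 1.0 + 1e-12
        assert update_charge(c, -80.0, False, p, decay_due=True) >= 0.0

    def test_ungated_adds_nothing(self):
        assert update_charge(2.0, M_head=-60.0, gated=False, params=PARAMS) == 2.0


class TestMemoryValue:
    def test_no_charge_means_no_memory(self):
        m = memory_value(0.0)
        assert m.multiplier == 1.0 and m.memory_time == 0.0

    def test_multiplier_two_at_e6_minus_one(self):
        assert memory_value(math.exp(6) - 1).multiplier == pytest.approx(2.0, rel=1e-12)

    def test_memory_time_is_log10(self):
        # C = 9 -> ln(10)/2.3026 = 1.0000 to 5 s.f.
        assert memory_value(9.0).memory_time == pytest.approx(1.0, abs=1e-4)

    @given(st.floats(min_value=0.0, max_value=1e6))
    @settings(max_examples=50, deadline=None)
    def test_multiplier_at_least_one(self, c):
        assert memory_value(c).multiplier >= 1.0


class TestEffectiveWeight:
    @pytest.mark.parametrize(
        "base, mult, expected", [(0.2, 1.0, 0.2), (0.6, 1.5, 0.9), (1.0, 2.0, 2.0)]
    )
    def test_products(self, base, mult, expected):
        assert effective_weight(base, mult) == pytest.approx(expected)

    def test_never_below_base(self):
        with pytest.raises(ValueError):
            effective_weight(0.5, 0.9)


def _cell_with_nmda(reg_len=60):
    params = CellParams("pyramidal", 0.6, 4.5, -6.0, -55.0)
    comps = []
    for k in range(3):
        c = Compartment(index=k, role="apical-dendrite")
        c.synapse_class = SynapseClass.NMDA if k == 1 else SynapseClass.NONE
        c.base_weight = 0.8 if k == 1 else 0.0
        c.make_registers(reg_len)
        comps.append(c)
    return CellState(params=params, compartments=comps)


class TestPlasticityStep:
    def test_no_arrivals_leave_charge_unchanged(self):
        cell = _cell_with_nmda()
        states = {1: LTPState(C=2.0)}
        states[1].refresh()
        plasticity_step(cell, states, PARAMS, arrivals=frozenset())
        assert states[1].C == 2.0

    def test_gated_arrival_composes_charge_and_memory(self):
        # single gated arrival with a 12 mV NMDA depolarization on C=0
        cell = _cell_with_nmda()
        cell.compartments[1].M.boxes[0] = -68.0
        cell.S[1] = -66.0  # above CaMT
        states = {1: LTPState()}
        plasticity_step(cell, states, PARAMS, arrivals={1})
        assert states[1].C == pytest.approx(math.expm1(0.12))
        assert states[1].M_mult == pytest.approx(1.0 + math.log1p(math.expm1(0.12)) / 6.0)
        assert states[1].M_mult == pytest.approx(1.0200, abs=1e-4)
        assert cell.m_mult[1] == states[1].M_mult

    def test_gate_soundness_no_charge_below_camt(self):
        cell = _cell_with_nmda()
        cell.compartments[1].M.boxes[0] = -68.0
        cell.S[1] = -70.0  # below CaMT: gate shut
        states = {1: LTPState()}
        plasticity_step(cell, states, PARAMS, arrivals={1})
        assert states[1].C == 0.0

    def test_repeated_arrivals_are_monotone_without_forgetting(self):
        cell = _cell_with_nmda()
        cell.compartments[1].M.boxes[0] = -70.0
        cell.S[1] = -60.0
        states = {1: LTPState()}
        prev_c, prev_m = 0.0, 1.0
        for _ in range(20):
            plasticity_step(cell, states, PARAMS, arrivals={1})
            assert states[1].C >= prev_c and states[1].M_mult >= prev_m
            prev_c, prev_m = states[1].C, states[1].M_mult

    def test_forgetting_converges_to_at_most_fq(self):
        cell = _cell_with_nmda()
        states = {1: LTPState(C=7.3)}
        for _ in range(20):
            plasticity_step(cell, states, PARAMS, arrivals=frozenset(), decay_due=True)
        assert 0.0 <= states[1].C <= PARAMS.FQ
        final = states[1].C
        plasticity_step(cell, states, PARAMS, arrivals=frozenset(), decay_due=True)
        assert states[1].C == final  # stays put once at or below FQ

    def test_rise_exceeds_per_step_decay(self):
        # rapid rise / very slow decrease asymmetry at default parameters:
        # one gated event at a typical NMDA depolarization raises M more
        # than one forgetting step lowers it from the same level
        cell = _cell_with_nmda()
        cell.compartments[1].M.boxes[0] = -68.0
        cell.S[1] = -66.0
        states = {1: LTPState(C=5.0)}
        states[1].refresh()
        m0 = states[1].M_mult
        plasticity_step(cell, states, PARAMS, arrivals={1})
        rise = states[1].M_mult - m0
        states2 = {1: LTPState(C=5.0)}
        states2[1].refresh()
        plasticity_step(cell, states2, PARAMS, arrivals=frozenset(), decay_due=True)
        decay = m0 - states2[1].M_mult
        assert rise > 0 and decay >= 0
        # per-cycle decay budget: one step each decay_every cycles
        assert rise > decay / PARAMS.decay_every


class TestParamValidation:
    def test_fq_below_one_rejected(self):
        with pytest.raises(Exception):
            PlasticityParams(FQ=0.5)

    def test_camt_above_rest_required(self):
        with pytest.raises(Exception):
            PlasticityParams(CaMT=-90.0)
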