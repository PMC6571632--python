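"""Shift registers, PSP templates, local potentials and spiking."""

import numpy as np
import pytest

from hipposim.neuron_core import (
    REST_POTENTIAL_MV,
    CellParams,
    CellState,
    Compartment,
    ConfigurationError,
    GlobalConstants,
    build_template,
    compartment_potential,
    fire_and_reset,
    inject_psp,
    make_register,
    soma_drive,
)

REST = REST_POTENTIAL_MV


class TestShiftRegister:
    def test_initialized_to_resting_potential(self):
        reg = make_register(200)
        assert len(reg) == 200
        assert np.all(reg.boxes == -80.0)

    def test_minimal_register(self):
        assert make_register(1).boxes.tolist() == [-80.0]

    def test_quiescent_advance_is_a_fixed_point(self):
        reg = make_register(50)
        for _ in range(50):
            reg.advance()
        assert np.all(reg.boxes == REST)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ConfigurationError):
            make_register(0)

    def test_advance_shifts_and_refills(self):
        reg = make_register(4)
        reg.boxes[:] = [-70.0, -75.0, -78.0, -79.0]
        reg.advance()
        assert reg.boxes.tolist() == [-75.0, -78.0, -79.0, REST]


class TestPSPTemplate:
    def test_excitatory_peak_attained_exactly(self):
        tpl = build_template("excitatory", 4.5, 2.0, 6.0)
        assert tpl.values.max() == pytest.approx(4.5, abs=0)
        assert np.count_nonzero(tpl.values == tpl.values.max()) == 1

    def test_inhibitory_peak(self):
        tpl = build_template("inhibitory", -6.0, 2.0, 6.0)
        assert tpl.values.min() == pytest.approx(-6.0, abs=0)

    def test_zero_peak_gives_null_template(self):
        tpl = build_template("excitatory", 0.0, 2.0, 6.0)
        assert np.all(tpl.values == 0.0)

    def test_bad_taus_rejected(self):
        with pytest.raises(ConfigurationError):
            build_template("excitatory", 4.5, 0.0, 6.0)
        with pytest.raises(ConfigurationError):
            build_template("excitatory", 4.5, 6.0, 2.0)

    def test_sign_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            build_template("excitatory", -1.0, 2.0, 6.0)

    def test_template_decays_below_cutoff(self):
        tpl = build_template("excitatory", 4.5, 2.0, 6.0)
        assert abs(tpl.values[-1]) >= 4.5e-3  # last retained box
        # continuation would be negligible
        t_next = tpl.support * 0.5
        cont = np.exp(-t_next / 6.0) - np.exp(-t_next / 2.0)
        assert cont * 4.5 < 0.05


class TestInjectPSP:
    def test_unit_injection_reproduces_template(self):
        reg = make_register(100)
        tpl = build_template("excitatory", 4.5, 2.0, 6.0)
        inject_psp(reg, tpl, weight=1.0, delay=0)
        assert np.allclose(reg.deviations()[: tpl.support], tpl.values)

    def test_zero_weight_is_identity(self):
        reg = make_register(100)
        tpl = build_template("excitatory", 4.5, 2.0, 6.0)
        inject_psp(reg, tpl, weight=0.0)
        assert np.all(reg.boxes == REST)

    def test_superposition_matches_convolution_oracle(self):
        # two events at delays 0 and 2: brute-force superposition oracle
        tpl = build_template("excitatory", 4.5, 2.0, 6.0)
        reg = make_register(120)
        inject_psp(reg, tpl, 1.0, delay=0)
        inject_psp(reg, tpl, 1.0, delay=2)
        expected = np.zeros(120)
        for d in (0, 2):
            expected[d : d + tpl.support] += tpl.values
        # equal up to IEEE rounding around the -80 mV baseline
        np.testing.assert_allclose(reg.deviations(), expected, rtol=0, atol=1e-12)
        assert reg.deviations()[2] == pytest.approx(tpl.values[2] + tpl.values[0])

    def test_order_independence(self):
        tpl = build_template("excitatory", 4.0, 2.0, 6.0)
        a, b = make_register(150), make_register(150)
        inject_psp(inject_psp(a, tpl, 0.5, 0), tpl, 1.5, 7)
        inject_psp(inject_psp(b, tpl, 1.5, 7), tpl, 0.5, 0)
        np.testing.assert_allclose(a.boxes, b.boxes, rtol=0, atol=1e-12)

    def test_tail_truncation_warns(self):
        reg = make_register(5)
        tpl = build_template("excitatory", 4.5, 2.0, 6.0)
        with pytest.warns(RuntimeWarning):
            inject_psp(reg, tpl, 1.0, delay=0)


def _cell(threshold=-55.0, n_comp=4, weights=(0.0, 1.0, 1.0, 0.2), reg_len=40):
    params = CellParams("pyramidal", 0.2, 4.5, -6.0, threshold)
    comps = []
    for k in range(n_comp):
        c = Compartment(index=k, role="soma" if k == 1 else "apical-dendrite")
        c.base_weight = weights[k]
        c.make_registers(reg_len)
        comps.append(c)
    return CellState(params=params, compartments=comps)


class TestLocalPotentialAndDrive:
    def test_rest_everywhere(self):
        cell = _cell()
        comp = cell.compartments[1]
        assert compartment_potential(comp) == REST
        assert soma_drive(cell) == REST

    def test_single_register_deviation(self):
        cell = _cell()
        comp = cell.compartments[1]
        comp.E.boxes[0] = -75.5
        assert compartment_potential(comp) == pytest.approx(-75.5)

    def test_excitation_and_inhibition_cancel(self):
        cell = _cell()
        comp = cell.compartments[1]
        comp.E.boxes[0] = -76.0
        comp.I.boxes[0] = -84.0
        assert compartment_potential(comp) == pytest.approx(REST)

    def test_single_term_drive(self):
        cell = _cell(weights=(0.0, 1.0, 0.0, 0.0))
        cell.S[1] = -70.0
        assert soma_drive(cell) == pytest.approx(-70.0)

    def test_weighted_sum_by_hand(self):
        # weights 1.0 and 0.2, both compartments depolarized by +10 mV
        cell = _cell(weights=(0.0, 1.0, 0.0, 0.2))
        cell.S[1] = -70.0
        cell.S[3] = -70.0
        assert soma_drive(cell) == pytest.approx(-80.0 + 12.0)


class TestFireAndReset:
    def test_spike_resets_registers(self):
        cell = _cell()
        cell.compartments[1].E.boxes[:] = -60.0
        spiked = fire_and_reset(cell, 10.0, drive=-54.0)
        assert spiked and cell.spike_times == [10.0]
        assert np.all(cell.compartments[1].E.boxes == REST)
        assert cell.refractory_cycles_left == 3

    def test_refractory_gate_blocks_spike(self):
        cell = _cell()
        cell.refractory_cycles_left = 2
        assert not fire_and_reset(cell, 10.0, drive=-54.0)
        assert cell.spike_times == []

    def test_subthreshold_drive_does_not_spike(self):
        cell = _cell()
        assert not fire_and_reset(cell, 10.0, drive=-56.0)

    def test_refractory_period_enforces_single_spike(self):
        # two supra-threshold cycles 0.5 ms apart -> exactly one spike
        cell = _cell()
        const = cell.constants
        t = 0.0
        spikes = 0
        for _ in range(2):
            if fire_and_reset(cell, t, drive=-54.0):
                spikes += 1
            else:
                cell.refractory_cycles_left -= 1
            t += const.dt
        assert spikes == 1


class TestGlobalConstants:
    def test_refractory_must_align_to_cycles(self):
        with pytest.raises(ConfigurationError):
            GlobalConstants(dt=0.5, refractory_ms=1.3)
        assert GlobalConstants().refractory_cycles == 3
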