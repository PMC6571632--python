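"""Engine semantics: convolution oracle, quiescence, determinism, lesions."""

import numpy as np
import pytest

import hipposim as h
from hipposim.engine import step_count
from hipposim.inputs import InputPopulation, InputSpikeTrains
from hipposim.microcircuit import (
    CA3_PCS,
    CellSpec,
    Connection,
    LesionEvent,
    LesionSchedule,
    NetworkConfig,
)
from hipposim.neuron_core import CellParams, ConfigurationError, SynapseClass, build_template


def single_cell_network(threshold=0.0, weight=0.5):
    """One pyramidal cell with a single AMPA synapse fed by one EC2 cell."""
    params = CellParams("pyramidal", 0.2, 4.5, -6.0, threshold)
    cells = {"P1": CellSpec("P1", "CA1", params)}
    conn = Connection(
        id="EC2->P1:14",
        source="EC2",
        target="P1",
        target_compartment=14,
        synapse_class=SynapseClass.AMPA,
        receptors=("AMPA",),
        base_weight=weight,
        delay_boxes=1,
        source_cells=(0,),
    )
    return NetworkConfig(cells=cells, connections=[conn])


def replay(times_ms, duration):
    pop = InputPopulation("EC2", n_cells=1, rate_peak=1.0)
    return {"EC2": InputSpikeTrains(pop, duration, [np.asarray(times_ms, float)])}


class TestStepCount:
    def test_ten_seconds_is_20000_cycles(self):
        assert step_count(10000.0, 0.5) == 20000

    def test_misaligned_duration_rejected(self):
        with pytest.raises(ConfigurationError):
            step_count(100.3, 0.5)


class TestConvolutionOracle:
    def test_register_engine_equals_direct_superposition(self):
        """Sub-threshold drive equals the brute-force superposition of the
        weighted PSP template over the input spike train, to floating point."""
        net = single_cell_network(weight=0.5)
        duration = 200.0
        spike_times = [3.0, 10.0, 10.5, 47.0, 120.0, 121.0, 122.5]
        res = h.run(
            net,
            duration,
            seed=0,
            input_trains=replay(spike_times, duration),
            record_drive=True,
        )
        assert res.spike_count("P1") == 0  # stays sub-threshold
        drive = res.drive_traces["P1"]
        tpl = build_template("excitatory", 4.5, 2.0, 6.0).values
        n = step_count(duration, 0.5)
        expected = np.zeros(n)
        for t in spike_times:
            ev = int(t // 0.5) + 1  # one conduction-delay box
            span = min(tpl.size, n - ev)
            expected[ev : ev + span] += tpl[:span]
        # equality up to IEEE accumulation rounding (~1e-14 at 80 mV scale)
        np.testing.assert_allclose(drive, -80.0 + 0.5 * expected, rtol=0, atol=1e-9)

    def test_single_spike_trace_is_the_weighted_template(self):
        net = single_cell_network(weight=1.0)
        duration = 60.0
        res = h.run(
            net, duration, seed=0, input_trains=replay([5.0], duration), record_drive=True
        )
        tpl = build_template("excitatory", 4.5, 2.0, 6.0).values
        ev = int(5.0 // 0.5) + 1
        seg = res.drive_traces["P1"][ev : ev + tpl.size] + 80.0
        np.testing.assert_allclose(seg, tpl, rtol=0, atol=1e-9)


class TestQuiescenceAndDeterminism:
    def test_no_input_fixed_point(self):
        net = h.build_default_network(seed=1)
        net.input_settings.update(ec_rate_peak=0.0, dg_rate_peak=0.0, ms_rate_peak=0.0)
        res = h.run(net, 1000.0, seed=1, record_drive=True)
        assert res.total_spikes() == 0
        for trace in res.drive_traces.values():
            assert np.all(trace == -80.0)

    def test_identical_seed_bit_identical_result(self):
        net = h.build_default_network(seed=3)
        a = h.run(net, 2000.0, seed=3)
        b = h.run(net, 2000.0, seed=3)
        for cid in a.cell_ids:
            assert np.array_equal(a.spike_trains[cid], b.spike_trains[cid])
            if cid in a.memory_traces:
                assert np.array_equal(a.memory_traces[cid], b.memory_traces[cid])

    def test_empty_schedule_equals_control(self):
        net = h.build_default_network(seed=4)
        control = h.run(net, 2000.0, seed=4)
        sham = h.run(net, 2000.0, seed=4, lesion_schedule=LesionSchedule([]))
        for cid in control.cell_ids:
            assert np.array_equal(control.spike_trains[cid], sham.spike_trains[cid])

    def test_all_14_cells_reported(self, paired_runs):
        control, _ = paired_runs[0]
        assert len(control.spike_trains) == 14


class TestRefractorinessAndCausality:
    def test_minimum_isi_at_least_two_ms(self, paired_runs):
        # 1.5 ms refraction + the spike cycle itself
        for control, pathology in paired_runs:
            for res in (control, pathology):
                for train in res.spike_trains.values():
                    if train.size > 1:
                        assert np.diff(train).min() >= 2.0

    def test_no_spike_before_first_input_plus_delay(self, paired_runs):
        for control, _ in paired_runs[:3]:
            first_input = min(
                tr.all_times()[0]
                for tr in control.input_trains.values()
                if tr.n_spikes
            )
            first_spike = min(
                (t[0] for t in control.spike_trains.values() if t.size),
                default=np.inf,
            )
            assert first_spike >= first_input + 0.5


class TestLesionedRuns:
    def test_deleted_synapse_injects_nothing(self):
        net = single_cell_network(weight=1.0)
        duration = 60.0
        sched = LesionSchedule([LesionEvent(0.0, "EC2->P1:14")])
        res = h.run(
            net,
            duration,
            seed=0,
            lesion_schedule=sched,
            input_trains=replay([5.0, 20.0], duration),
            record_drive=True,
        )
        assert np.all(res.drive_traces["P1"] == -80.0)

    def test_deletion_series_monotone_and_complete(self, paired_runs):
        _, pathology = paired_runs[0]
        d = pathology.deletion_series
        assert np.all(np.diff(d) >= 0)
        assert d[0] == 0 and d[-1] == 44  # all CA3 afferents deleted

    def test_full_deletion_drives_ca3_toward_silence(self, paired_runs):
        # after the last deletion, CA3 firing approaches the no-input baseline
        for control, pathology in paired_runs[:5]:
            late = lambda res: sum(
                np.count_nonzero(res.spike_trains[c] >= 9000.0) for c in CA3_PCS
            )
            assert late(pathology) < late(control)
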