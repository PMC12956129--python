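"""Mass-balance simulator: flow integration, conservation, faults, noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solvex import ActuationError, VirtualDevice
from solvex.errors import SimulationFault
from solvex.virtual import COMPONENTS


def total_volume(dev):
    return (
        sum(dev.stock_levels.values())
        + dev.premix.volume
        + dev.tissue.volume
        + dev.waste_volume
    )


def total_ethanol(dev):
    by_pump = {s.pump_id: s.concentration for s in dev.stocks}
    return (
        sum(lvl * by_pump[pid] for pid, lvl in dev.stock_levels.items())
        + dev.premix.ethanol
        + dev.tissue.ethanol
        + dev.waste_ethanol
    )


class TestAdvance:
    def test_perfect_mixing_of_water_into_seventy_percent(self, make_device):
        dev = make_device()
        # preload premix: 100 mL at 0.70 via pump 2 (EtOH70)
        dev.pump_on(2)
        dev.advance(100 / 1.10)
        dev.pump_off(2)
        assert dev.premix.volume == pytest.approx(100.0)
        assert dev.premix.concentration == pytest.approx(0.70)
        # pump in 71.43 mL of water
        dev.pump_on(1)
        dev.advance(71.43 / 1.10)
        dev.pump_off(1)
        assert dev.premix.volume == pytest.approx(171.43)
        assert dev.premix.concentration == pytest.approx(0.4083, abs=1e-4)

    def test_single_source_fill_takes_stock_concentration(self, make_device):
        dev = make_device()
        dev.pump_on(3)  # EtOH100
        dev.advance(10.0)
        assert dev.premix.volume == pytest.approx(11.0)
        assert dev.premix.concentration == pytest.approx(1.0)

    def test_no_actuation_is_identity(self, make_device):
        dev = make_device()
        before = dev.snapshot()
        dev.advance(1234.5)
        after = dev.snapshot()
        assert (before.premix_volume, before.tissue_volume, before.stock_levels) == (
            after.premix_volume,
            after.tissue_volume,
            after.stock_levels,
        )

    def test_transfer_then_drain_moves_liquid_through(self, make_device):
        dev = make_device()
        dev.pump_on(2)
        dev.advance(250 / 1.10)
        dev.pump_off(2)
        dev.top_valve(True)
        dev.advance(60)  # 10 mL/s empties 250 mL premix in 25 s
        dev.top_valve(False)
        assert dev.premix.volume == pytest.approx(0.0, abs=1e-9)
        assert dev.tissue.volume == pytest.approx(250.0)
        dev.drain(True)
        dev.advance(30)
        dev.drain(False)
        assert dev.tissue.volume == pytest.approx(0.0, abs=1e-9)
        assert dev.waste_volume == pytest.approx(250.0)

    def test_pump_stops_silently_when_stock_runs_dry(self):
        dev = VirtualDevice(initial_stock_volume=5.0)
        dev.pump_on(1)
        dev.advance(100)
        assert dev.stock_levels[1] == pytest.approx(0.0)
        assert dev.premix.volume == pytest.approx(5.0)
        assert any("low" in w for w in dev.warnings)

    def test_overflow_is_a_fault_not_clipping(self, make_device):
        dev = make_device(premix_capacity=20.0)
        dev.pump_on(1)
        with pytest.raises(SimulationFault, match="overflow"):
            dev.advance(60)


class TestFaultInjection:
    def test_dead_pump_fails_self_test_and_command(self, make_device):
        dev = make_device()
        dev.inject_fault("pump2", "dead")
        assert dev.self_test("pump2").startswith("FAULT")
        with pytest.raises(ActuationError):
            dev.pump_on(2)

    def test_degraded_drain_halves_flow(self, make_device):
        nominal = make_device()
        slow = make_device()
        slow.inject_fault("drain_valve", "degraded", rate_multiplier=0.5)
        for dev in (nominal, slow):
            dev.pump_on(1)
            dev.advance(250 / 1.10)
            dev.pump_off(1)
            dev.top_valve(True)
            dev.advance(30)
            dev.top_valve(False)
            dev.drain(True)
        nominal.advance(10)  # 250 mL at 25 mL/s
        slow.advance(10)
        assert nominal.tissue.volume == pytest.approx(0.0, abs=1e-6)
        assert slow.tissue.volume == pytest.approx(125.0)
        slow.advance(10)  # 2x nominal time empties it
        assert slow.tissue.volume == pytest.approx(0.0, abs=1e-6)

    def test_healthy_device_passes_all_self_tests(self, make_device):
        dev = make_device()
        assert [dev.self_test(c) for c in COMPONENTS] == ["OK"] * 6

    def test_unknown_component_raises(self, make_device):
        with pytest.raises(ActuationError):
            make_device().inject_fault("pump9", "dead")


class TestSnapshot:
    def test_snapshot_is_detached_copy(self, make_device):
        dev = make_device()
        snap = dev.snapshot()
        dev.pump_on(1)
        dev.advance(10)
        assert snap.premix_volume == 0.0
        assert dev.snapshot().premix_volume > 0

    def test_snapshots_without_commands_are_equal(self, make_device):
        dev = make_device()
        assert dev.snapshot() == dev.snapshot()

    def test_snapshot_fields_satisfy_mass_balance(self, make_device):
        dev = make_device()
        dev.pump_on(3)
        dev.advance(42)
        snap = dev.snapshot()
        total = (
            sum(snap.stock_levels.values())
            + snap.premix_volume
            + snap.tissue_volume
            + snap.waste_volume
        )
        assert total == pytest.approx(3 * 4000.0)


command_strategy = st.lists(
    st.one_of(
        st.tuples(st.just("pump_on"), st.integers(1, 3)),
        st.tuples(st.just("pump_off"), st.integers(1, 3)),
        st.tuples(st.just("top_valve"), st.booleans()),
        st.tuples(st.just("drain"), st.booleans()),
        st.tuples(st.just("advance"), st.floats(0.1, 120.0)),
    ),
    max_size=40,
)


def apply_commands(dev, commands):
    for op, arg in commands:
        getattr(dev, op)(arg)


class TestConservationProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(commands=command_strategy)
    def test_volume_and_ethanol_conserved_under_random_actuation(self, commands):
        dev = VirtualDevice(initial_stock_volume=4000.0, premix_capacity=1e9,
                            tissue_capacity=1e9)
        v0, e0 = total_volume(dev), total_ethanol(dev)
        apply_commands(dev, commands)
        assert total_volume(dev) == pytest.approx(v0, abs=1e-6)
        assert total_ethanol(dev) == pytest.approx(e0, abs=1e-6)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(commands=command_strategy)
    def test_concentrations_stay_within_stock_range(self, commands):
        dev = VirtualDevice(initial_stock_volume=4000.0, premix_capacity=1e9,
                            tissue_capacity=1e9)
        lo = min(s.concentration for s in dev.stocks)
        hi = max(s.concentration for s in dev.stocks)
        for op, arg in commands:
            getattr(dev, op)(arg)
            for c in (dev.premix, dev.tissue):
                assert lo - 1e-9 <= c.concentration <= hi + 1e-9

    def test_same_seed_and_commands_give_identical_state(self):
        runs = []
        for _ in range(2):
            dev = VirtualDevice(initial_stock_volume=4000.0, pump_rate_sd=0.02, seed=5)
            dev.pump_on(1)
            dev.advance(30)
            dev.pump_off(1)
            dev.pump_on(3)
            dev.advance(45)
            runs.append(dev.snapshot())
        assert runs[0] == runs[1]


class TestNoiseModel:
    def test_dispense_cv_matches_calibration_spread(self):
        # repeated 10 s dispenses with relative rate noise 0.02/1.10 should
        # show a volume CV near 0.0182, within a +/- 2 SD sampling envelope
        dev = VirtualDevice(
            initial_stock_volume=100000.0,
            premix_capacity=1e9,
            pump_rate_sd=0.02,
            seed=7,
        )
        volumes = []
        prev = 0.0
        for _ in range(60):
            dev.pump_on(1)
            dev.advance(10)
            dev.pump_off(1)
            volumes.append(dev.premix.volume - prev)
            prev = dev.premix.volume
        volumes = np.asarray(volumes)
        cv = volumes.std(ddof=1) / volumes.mean()
        true_cv = 0.02 / 1.10
        envelope = 2 * true_cv / np.sqrt(2 * (len(volumes) - 1))
        assert abs(cv - true_cv) <= envelope
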