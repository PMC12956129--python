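"""Run execution: progress, pause/abort, faults, flush, sanity check, replay."""

import pytest

from solvex import (
    DeviceConfig,
    Routine,
    RunController,
    ScriptedCommand,
    SimulatedClock,
    Step,
    VirtualDevice,
    compile_routine,
    flush_system,
    replay_log,
    run,
    sanity_check,
)


def short_routine(concs_pct=(50, 85), duration_min=2.0):
    return Routine(
        routine_id=4,
        steps=tuple(
            Step(target_concentration=c / 100, duration=duration_min) for c in concs_pct
        ),
    )


class TestRun:
    def test_post_stain_run_ends_in_absolute_ethanol(self, pi_store, make_device):
        sched = compile_routine(pi_store[2])
        dev = make_device()
        log = run(sched, dev)
        assert log.status == "completed"
        snap = dev.snapshot()
        assert snap.tissue_concentration == pytest.approx(1.0, abs=1e-9)
        # delivered volume is exact up to the tick-quantized pump times
        assert snap.tissue_volume == pytest.approx(250.0, abs=0.25)

    def test_programmed_series_reproduced_at_each_soak(self, pi_store, make_device):
        sched = compile_routine(pi_store[1])
        dev = make_device()
        concs = []
        run(sched, dev, progress=lambda rec: concs.append(dev.snapshot().tissue_concentration))
        programmed = [s.target_concentration for s in pi_store[1]]
        # one progress record per soak start, plus a final completion record
        for got, want in zip(concs[: len(programmed)], programmed):
            assert got == pytest.approx(want, abs=0.005)

    def test_tissue_submerged_during_every_soak(self, pi_store, make_device):
        cfg = DeviceConfig()
        sched = compile_routine(pi_store[2], cfg)
        dev = make_device()
        volumes = []
        run(sched, dev, progress=lambda rec: volumes.append(dev.snapshot().tissue_volume))
        # full exchange volume, less at most two controller ticks of pump flow
        assert all(v >= cfg.exchange_volume - 0.25 for v in volumes)

    def test_every_action_logged_once_on_completion(self, pi_store, make_device):
        sched = compile_routine(pi_store[2])
        log = run(sched, make_device())
        logged = [
            (r.detail["action"], r.detail["target"], r.detail["scheduled_t"])
            for r in log.actions()
            if "scheduled_t" in r.detail
        ]
        scheduled = [(a.kind, a.target, a.start_time) for a in sched.actions]
        assert logged == scheduled

    def test_progress_reports_step_and_remaining_time(self, make_device):
        sched = compile_routine(short_routine())
        records = []
        run(sched, make_device(), progress=records.append)
        assert records[0]["step"] == 1 and records[0]["n_steps"] == 2
        assert records[0]["remaining_s"] > records[-1]["remaining_s"]


class TestPauseAbort:
    def test_abort_during_step_drops_later_steps_and_drives_safe_state(
        self, pi_store, make_device
    ):
        sched = compile_routine(pi_store[2])
        # abort mid-way through step 3's soak
        t_abort = sched.per_step_summaries[2].soak_start + 60.0
        ctl = RunController([ScriptedCommand(t_abort, "abort")])
        dev = make_device()
        log = run(sched, dev, controller=ctl)
        assert log.status == "aborted"
        steps_seen = {
            r.detail.get("step") for r in log.actions() if r.detail.get("step")
        }
        assert max(steps_seen) <= 4  # step 4 prefetch dosing may have started
        soaks = [r for r in log.actions() if r.detail["action"] == "soak_wait"]
        assert len(soaks) == 3
        snap = dev.snapshot()
        assert snap.pumps_on == () and not snap.top_valve_open and not snap.drain_open

    def test_pause_resume_preserves_total_soak_time(self, make_device):
        sched = compile_routine(short_routine())
        t0 = sched.per_step_summaries[0].soak_start + 10.0
        ctl = RunController(
            [ScriptedCommand(t0, "pause"), ScriptedCommand(t0 + 300.0, "resume")]
        )
        dev_p = make_device()
        log_p = run(sched, dev_p, controller=ctl)
        dev_u = make_device()
        log_u = run(sched, dev_u, controller=RunController())
        assert log_p.status == log_u.status == "completed"
        # identical end state, shifted in time by the pause
        assert dev_p.snapshot().tissue_concentration == pytest.approx(
            dev_u.snapshot().tissue_concentration
        )
        end_p = max(r.time for r in log_p.actions())
        end_u = max(r.time for r in log_u.actions())
        assert end_p - end_u == pytest.approx(300.0, abs=1.0)

    def test_pause_during_dosing_delivers_remaining_volume_on_resume(self, make_device):
        cfg = DeviceConfig()
        sched = compile_routine(short_routine(), cfg)
        # first pump_on for step 1 starts at t=0; pause 20 s into it
        ctl = RunController(
            [ScriptedCommand(20.0, "pause"), ScriptedCommand(120.0, "resume")]
        )
        dev = make_device()
        log = run(sched, dev, controller=ctl)
        assert log.status == "completed"
        # step 1 premix still hits its 50% target from full delivered volumes
        concs = [
            r.detail
            for r in log.records
            if r.kind == "progress" and r.detail["step"] == 1
        ]
        assert concs
        assert dev.snapshot().tissue_concentration == pytest.approx(0.85, abs=0.005)

    def test_commands_after_completion_are_no_ops(self, make_device):
        sched = compile_routine(short_routine())
        ctl = RunController()
        log = run(sched, make_device(), controller=ctl)
        assert log.status == "completed"
        ctl.abort()  # nothing polls a finished run; state must not change
        assert log.status == "completed"


class TestFaults:
    def test_dead_pump_faults_run_into_safe_state(self, pi_store, make_device):
        sched = compile_routine(pi_store[2])
        dev = make_device()
        dev.inject_fault("pump2", "dead")
        log = run(sched, dev)
        assert log.status == "faulted"
        assert any(r.kind == "fault" for r in log.records)
        assert log.actions()[-1].detail["action"] == "safe_state"
        snap = dev.snapshot()
        assert snap.pumps_on == () and not snap.top_valve_open and not snap.drain_open


class TestFlush:
    def test_flush_empties_both_containers(self, make_device):
        dev = make_device()
        dev.pump_on(2)
        dev.advance(100 / 1.10)
        dev.pump_off(2)
        dev.top_valve(True)
        dev.advance(5)
        dev.top_valve(False)
        assert dev.premix.volume > 0 and dev.tissue.volume > 0
        log = flush_system(dev, DeviceConfig(), duration=600.0)
        assert log.status == "completed"
        assert dev.premix.volume == pytest.approx(0.0, abs=1e-6) or dev.premix.volume < 1e-3
        assert dev.tissue.volume < 1e-3

    def test_flush_logs_one_open_and_close_per_valve(self, make_device):
        log = flush_system(make_device(), DeviceConfig(), duration=60.0)
        kinds = [r.detail["action"] for r in log.actions()]
        for k in ("top_valve_open", "top_valve_close", "drain_open", "drain_close"):
            assert kinds.count(k) == 1

    def test_flush_with_dead_pump_faults_but_closes_valves(self, make_device):
        dev = make_device()
        dev.inject_fault("pump2", "dead")
        log = flush_system(dev, DeviceConfig(), duration=60.0)
        assert log.status == "faulted"
        snap = dev.snapshot()
        assert not snap.top_valve_open and not snap.drain_open and snap.pumps_on == ()

    def test_non_positive_duration_rejected(self, make_device):
        with pytest.raises(ValueError):
            flush_system(make_device(), DeviceConfig(), duration=0.0)


class TestSanityCheck:
    def test_healthy_device_reports_six_ok_in_fixed_order(self, make_device):
        report = sanity_check(make_device())
        assert [s.component for s in report] == [
            "pump1",
            "pump2",
            "pump3",
            "top_valve",
            "drain_valve",
            "input",
        ]
        assert all(s.ok for s in report)

    def test_injected_drain_fault_reported_others_ok(self, make_device):
        dev = make_device()
        dev.inject_fault("drain_valve", "dead")
        report = {s.component: s.ok for s in sanity_check(dev)}
        assert report["drain_valve"] is False
        assert sum(report.values()) == 5

    def test_self_test_has_no_side_effects(self, make_device):
        dev = make_device()
        before = dev.snapshot()
        sanity_check(dev)
        assert dev.snapshot() == before


class TestReplay:
    def test_replaying_log_reproduces_final_state(self, pi_store, make_device):
        sched = compile_routine(pi_store[2])
        dev = make_device()
        log = run(sched, dev, SimulatedClock())
        twin = make_device()
        replay_log(log, twin)
        assert twin.snapshot().tissue_concentration == pytest.approx(
            dev.snapshot().tissue_concentration, abs=1e-9
        )
        assert twin.snapshot().waste_volume == pytest.approx(
            dev.snapshot().waste_volume, abs=1e-6
        )

    def test_log_serializes_to_jsonl(self, make_device):
        sched = compile_routine(short_routine())
        log = run(sched, make_device())
        lines = log.to_jsonl().strip().splitlines()
        assert lines[-1] == '{"final_status": "completed"}'
        assert len(lines) == len(log.records) + 1
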