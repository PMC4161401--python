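"""Stop criteria and the closed-loop engine."""

import numpy as np
import pytest

import cytoloop as cl
from cytoloop.control import (
    Criterion,
    CycleData,
    Phase,
    bundled_protocol,
    evaluate_criterion,
    load_protocol,
    register_criterion,
    run_experiment,
)

from conftest import experiment_rig


def cycle(t_min, counts, fluor=None):
    """Build a CycleData; fluor maps (fov, cell) -> raw value (bg 50)."""
    fluor = fluor or {}
    return CycleData(
        t_min=t_min,
        fov_counts=counts,
        cell_fluor={k: (v, v - 50.0) for k, v in fluor.items()},
    )


class TestCountCriterion:
    def test_quarter_increase_met(self):
        history = [cycle(0, {0: 100}), cycle(5, {0: 125})]
        res = evaluate_criterion(Criterion("count", threshold=0.25), history, "phase_start", 0)
        assert res.met

    def test_just_below_not_met(self):
        history = [cycle(0, {0: 100}), cycle(5, {0: 124})]
        assert not evaluate_criterion(
            Criterion("count", threshold=0.25), history, "phase_start", 0
        ).met

    def test_no_history_not_met(self):
        assert not evaluate_criterion(Criterion("count"), [], "phase_start", 0).met


class TestFluorescenceCriterion:
    def test_half_of_cells_half_increase(self):
        """4 of 8 cells at >= 1.5x their reference fluorescence."""
        ref = {(0, i): 100.0 for i in range(8)}
        now = {(0, i): (150.0 if i < 4 else 120.0) for i in range(8)}
        history = [cycle(0, {0: 8}, ref), cycle(5, {0: 8}, now)]
        crit = Criterion("fluorescence", fraction=0.5, threshold=0.5)
        assert evaluate_criterion(crit, history, "phase_start", 0).met

    def test_three_of_eight_not_met(self):
        ref = {(0, i): 100.0 for i in range(8)}
        now = {(0, i): (150.0 if i < 3 else 120.0) for i in range(8)}
        history = [cycle(0, {0: 8}, ref), cycle(5, {0: 8}, now)]
        crit = Criterion("fluorescence", fraction=0.5, threshold=0.5)
        assert not evaluate_criterion(crit, history, "phase_start", 0).met

    def test_over_background_variant(self):
        ref = {(0, i): 50.0 for i in range(4)}
        now = {(0, i): (80.0 if i < 1 else 55.0) for i in range(4)}
        history = [cycle(0, {0: 4}, ref), cycle(5, {0: 4}, now)]
        crit = Criterion("fluorescence_over_background", fraction=0.25, threshold=0.25)
        # 1 of 4 cells rose by 30 >= 0.25 * background(40)
        assert evaluate_criterion(crit, history, "phase_start", 0, background_level=40.0).met
        assert not evaluate_criterion(crit, history, "phase_start", 0, background_level=None).met

    def test_per_fov_pass_map(self):
        ref = {(0, 1): 100.0, (1, 2): 100.0}
        now = {(0, 1): 200.0, (1, 2): 101.0}
        history = [cycle(0, {0: 1, 1: 1}, ref), cycle(5, {0: 1, 1: 1}, now)]
        res = evaluate_criterion(
            Criterion("fluorescence", fraction=0.5, threshold=0.5), history, "phase_start", 0
        )
        assert res.fov_pass == {0: True, 1: False}


class TestSteadinessCriterion:
    def _history(self, slopes_by_cell, n=6, dt=5.0, level=200.0):
        hist = []
        for k in range(n):
            fluor = {
                (0, cid): level + s * dt * k for cid, s in slopes_by_cell.items()
            }
            hist.append(cycle(k * dt, {0: len(slopes_by_cell)}, fluor))
        return hist

    def test_flat_cells_steady(self):
        hist = self._history({1: 0.0, 2: 0.001})
        assert evaluate_criterion(Criterion("steadiness", fraction=0.6), hist, "previous", 0).met

    def test_rising_cells_not_steady(self):
        # slope 2/min on a bg-subtracted level of ~60: above 3%/min
        hist = self._history({1: 2.0, 2: 2.0}, level=60.0)
        assert not evaluate_criterion(Criterion("steadiness", fraction=0.6), hist, "previous", 0).met

    def test_needs_five_points(self):
        hist = self._history({1: 0.0}, n=4)
        assert not evaluate_criterion(Criterion("steadiness"), hist, "previous", 0).met

    def test_window_confined_to_phase(self):
        hist = self._history({1: 0.0}, n=6)
        assert not evaluate_criterion(Criterion("steadiness"), hist, "previous", 3).met


class TestDoublingsCriterion:
    @pytest.mark.parametrize("now,met", [(199, False), (200, True)])
    def test_two_doublings_threshold(self, now, met):
        history = [cycle(0, {0: 50}), cycle(5, {0: now})]
        res = evaluate_criterion(Criterion("doublings", threshold=2), history, "phase_start", 0)
        assert res.met is met


class TestElapsedCriterion:
    def test_fixed_time_phase(self):
        history = [cycle(0, {0: 5}), cycle(29, {0: 5})]
        assert not evaluate_criterion(Criterion("elapsed", threshold=30), history, "phase_start", 0).met
        history.append(cycle(30, {0: 5}))
        assert evaluate_criterion(Criterion("elapsed", threshold=30), history, "phase_start", 0).met


class TestRegistry:
    def test_unknown_criterion_raises(self):
        with pytest.raises(KeyError):
            evaluate_criterion(Criterion("no_such_rule"), [cycle(0, {0: 1})], "previous", 0)

    def test_custom_rule_registration(self):
        @register_criterion("always")
        def _always(criterion, history, ref, background, phase_start_idx):
            from cytoloop.control import CriterionResult

            return CriterionResult(True, {f: True for f in history[-1].fov_counts})

        assert evaluate_criterion(Criterion("always"), [cycle(0, {0: 1})], "previous", 0).met


class TestProtocolIO:
    def test_load_roundtrip(self, tmp_path):
        text = """
phases:
  - {medium: raffinose, criterion: {name: count, threshold: 0.25}, timeout_min: 90}
  - {medium: galactose, criterion: {name: fluorescence, fraction: 0.5, threshold: 0.5},
     fov_policy: drop_failing_and_rescale}
channels:
  - {name: phase, filter_slot: 0, exposure_ms: 10}
  - {name: yfp, filter_slot: 1, exposure_ms: 75}
n_af: 1
"""
        path = tmp_path / "p.yaml"
        path.write_text(text)
        prot = load_protocol(path)
        assert len(prot.phases) == 2
        assert prot.phases[0].timeout_min == 90
        assert prot.phases[1].fov_policy == "drop_failing_and_rescale"
        assert prot.n_af == 1
        assert prot.channels[1].exposure_ms == 75.0

    def test_bundled_protocols_parse(self):
        for name in ("maturation", "memory", "conventional_maturation"):
            prot = bundled_protocol(name)
            assert len(prot.phases) >= 3

    def test_invalid_phase_rejected(self):
        with pytest.raises(ValueError):
            Phase("p", "galactose", Criterion("count"), reference="nonsense")


class TestRunExperiment:
    def test_immediate_timeout_fires_notification_once(self):
        scope, fovs = experiment_rig(seed=31)
        prot = load_protocol(
            {
                "phases": [
                    {
                        "medium": "raffinose",
                        "criterion": {"name": "count", "threshold": 5.0},
                        "timeout_min": 1e-6,
                    }
                ],
                "channels": [{"name": "phase", "exposure_ms": 10}],
            }
        )
        notes = []
        res = run_experiment(prot, scope, fovs, notify=notes.append)
        assert res.status == "timeout"
        assert res.n_cycles == 1
        assert len(notes) == 1
        assert notes[0]["status"] == "timeout"

    def test_no_valid_fovs(self):
        scope, _ = experiment_rig(seed=31)
        prot = bundled_protocol("maturation")
        res = run_experiment(prot, scope, [])
        assert res.status == "no_valid_fovs"

    def test_maturation_protocol_traverses_three_phases(self):
        scope, fovs = experiment_rig(seed=11)
        res = run_experiment(bundled_protocol("maturation"), scope, fovs, max_cycles=200)
        assert res.status == "completed"
        assert [iv.name for iv in res.phase_intervals] == ["growth", "induction", "chase"]
        # intervals partition [0, end] contiguously
        assert res.phase_intervals[0].start_min == pytest.approx(0.0)
        for a, b in zip(res.phase_intervals, res.phase_intervals[1:]):
            assert a.end_min == pytest.approx(b.start_min)
        assert res.phase_intervals[-1].end_min == pytest.approx(res.elapsed_min)
        assert len([n for n in (res.notification,) if n]) == 1

    def test_memory_protocol_second_induction_shorter(self):
        scope, fovs = experiment_rig(seed=12, shape=(256, 256), max_cells=8)
        res = run_experiment(bundled_protocol("memory"), scope, fovs, max_cycles=300)
        assert res.status == "completed"
        names = [iv.name for iv in res.phase_intervals]
        assert names == ["growth", "induction1", "repression", "induction2"]
        first = res.phase_intervals[1].duration_min
        second = res.phase_intervals[3].duration_min
        assert second < first

    def test_keep_all_policy_constant_fov_set(self):
        scope, fovs = experiment_rig(seed=11)
        res = run_experiment(bundled_protocol("maturation"), scope, fovs, max_cycles=200)
        assert len(res.retained_fov_history) == 1  # never changed

    def test_realized_period_at_least_planned(self):
        scope, fovs = experiment_rig(seed=21)
        res = run_experiment(bundled_protocol("maturation"), scope, fovs, max_cycles=200)
        times = sorted({r.t_min for tr in res.trajectories for r in tr.records})
        deltas = np.diff(times)
        assert (deltas >= res.period_history_s[-1] / 60.0 - 1e-6).all()

    def test_drop_failing_and_rescale_shrinks_period(self):
        # 4 FOVs; only "memory" cells induce within the experiment (naive
        # delay is effectively infinite, re-induction fast).  Marking the
        # leftmost 60% of cells makes the population criterion pass while
        # the rightmost FOV(s) fail it on their own and get dropped.
        scope, fovs = experiment_rig(seed=13, n_fovs=4, n_cells=60, chamber=260.0)
        half = 192 * 0.205 / 2.0  # FOV half-extent, um
        imaged = [
            c for c in scope.population.cells
            if any(abs(c.x - f.x) < half and abs(c.y - f.y) < half for f in fovs)
        ]
        xs = sorted(c.x for c in imaged)
        cutoff = xs[int(0.65 * len(xs))]
        for cell in scope.population.cells:
            cell.induced_before = cell.x < cutoff
        scope.population.config = cl.SimulationConfig(
            seed=13, chamber_um=(260.0, 260.0), doubling_time_min=1e6,
            induction_delay_naive_min=1e6, reinduction_factor=1e-5,
            motion_sd_um=0.0,
        )
        prot = load_protocol(
            {
                "phases": [
                    {
                        "medium": "galactose",
                        "criterion": {"name": "fluorescence", "fraction": 0.5, "threshold": 0.5},
                        "timeout_min": 3000,
                        "fov_policy": "drop_failing_and_rescale",
                    },
                    {
                        "medium": "galactose",
                        "criterion": {"name": "elapsed", "threshold": 10},
                        "timeout_min": 3000,
                    },
                ],
                "channels": [
                    {"name": "phase", "filter_slot": 0, "exposure_ms": 10},
                    {"name": "yfp", "filter_slot": 1, "exposure_ms": 75},
                ],
                "period_min": 5.0,
            }
        )
        res = run_experiment(prot, scope, fovs, max_cycles=400)
        assert res.status == "completed"
        if len(res.retained_fov_history) > 1:  # a drop actually occurred
            assert len(res.retained_fov_history[-1]) < len(res.retained_fov_history[0])
            assert res.period_history_s[-1] <= res.period_history_s[0]
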