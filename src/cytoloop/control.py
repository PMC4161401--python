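"""Closed-loop experiment control.

An experiment is an ordered list of *phases*, each binding a media inlet to
a stop criterion, a reference timepoint and a timeout.  Every acquisition
cycle the engine visits the selected fields of view in route order,
autofocuses per policy, snaps each channel, segments the phase-contrast
image, maps cells to the previous frame and extracts features; it then
evaluates the current phase's criterion against the chosen reference
(experiment start, phase start, or the previous timepoint).  When the
criterion is met the engine switches media and moves to the next phase (or
ends the experiment after the last); a phase may also drop the FOVs that
failed the criterion on their own and re-plan the acquisition period for
the survivors.  If a phase outlasts its timeout the experiment ends with a
timeout status.  Exactly one completion notification is emitted, through a
pluggable callback.

Built-in stop criteria (registry extensible via :func:`register_criterion`):

``count``
    population cell count grew by the threshold fraction c over reference.
``fluorescence``
    at least a fraction f of cells raised their raw fluorescence by >= c
    relative to their reference value.
``fluorescence_over_background``
    at least f of cells raised their background-subtracted fluorescence by
    >= c times the estimated autofluorescence level over reference.
``steadiness``
    at least f of cells have a last-5-point least-squares slope within
    epsilon of zero (relative to their current level).
``doublings``
    cell count reached 2^d times the phase-start count.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from .fov_select import FieldOfView
from .hal_sim import VirtualMicroscope
from .latency import Channel, LatencyModel, min_resolution_adaptive, rescale_on_drop
from .segmentation import SegmentationParams, segment
from .tracking import CellTrajectory, Tracker

__all__ = [
    "Criterion",
    "Phase",
    "ExperimentProtocol",
    "ExperimentResult",
    "CycleData",
    "evaluate_criterion",
    "register_criterion",
    "run_experiment",
    "load_protocol",
    "bundled_protocol",
]

logger = logging.getLogger("cytoloop.control")

REFERENCES = ("experiment_start", "phase_start", "previous")
FOV_POLICIES = ("keep_all", "drop_failing", "drop_failing_and_rescale")

#: steadiness tolerance: |slope| <= epsilon * |current level|, slope per
#: minute.  The 5-point least-squares slope of a flat trajectory sampled
#: every 5 min with 10% multiplicative noise has a noise floor of about
#: 0.6% of the level per minute, so the tolerance must sit well above that.
STEADINESS_EPSILON = 0.03


@dataclass(frozen=True)
class Criterion:
    """A named stop rule with its parameters."""

    name: str
    fraction: float = 0.5  # f: fraction of cells that must pass
    threshold: float = 0.25  # c: change threshold (or d for doublings)
    epsilon: float = STEADINESS_EPSILON

    def __post_init__(self):
        if not 0 < self.fraction <= 1:
            raise ValueError("criterion fraction must lie in (0, 1]")


@dataclass(frozen=True)
class Phase:
    """One experiment phase."""

    name: str
    medium: str
    criterion: Criterion
    reference: str = "phase_start"
    timeout_min: float = 600.0
    fov_policy: str = "keep_all"

    def __post_init__(self):
        if self.reference not in REFERENCES:
            raise ValueError(f"reference must be one of {REFERENCES}")
        if self.fov_policy not in FOV_POLICIES:
            raise ValueError(f"fov_policy must be one of {FOV_POLICIES}")
        if self.timeout_min <= 0:
            raise ValueError("timeout must be > 0")


@dataclass(frozen=True)
class ExperimentProtocol:
    """Ordered phases plus acquisition configuration."""

    phases: tuple[Phase, ...]
    channels: tuple[Channel, ...]
    n_af: int | str = "all"  # FOVs autofocused per cycle ("all" or an int)
    period_min: float | None = None  # optional floor on the cycle period
    seed: int = 0

    def __post_init__(self):
        if len(self.phases) == 0:
            raise ValueError("protocol needs at least one phase")
        if len(self.channels) == 0:
            raise ValueError("protocol needs at least one channel")


@dataclass
class CycleData:
    """Measurements of one acquisition cycle."""

    t_min: float
    fov_counts: dict[int, int]
    # (fov_id, local cell id) -> (raw mean fluorescence, background-subtracted)
    cell_fluor: dict[tuple[int, int], tuple[float, float]]

    @property
    def total_count(self) -> int:
        return sum(self.fov_counts.values())


@dataclass(frozen=True)
class CriterionResult:
    met: bool
    fov_pass: dict[int, bool]
    detail: str = ""


CriterionFn = Callable[..., CriterionResult]
_CRITERIA: dict[str, CriterionFn] = {}


def register_criterion(name: str) -> Callable[[CriterionFn], CriterionFn]:
    """Decorator registering a stop-criterion rule under ``name``."""

    def deco(fn: CriterionFn) -> CriterionFn:
        _CRITERIA[name] = fn
        return fn

    return deco


def _resolve_reference(
    history: Sequence[CycleData], reference: str, phase_start_idx: int
) -> CycleData | None:
    if len(history) == 0:
        return None
    if reference == "experiment_start":
        return history[0]
    if reference == "phase_start":
        return history[phase_start_idx]
    if len(history) < 2:
        return None
    return history[-2]


@register_criterion("count")
def _count_rule(criterion, history, ref, background, phase_start_idx):
    now = history[-1]
    if ref is None:
        return CriterionResult(False, {}, "no reference cycle yet")
    need = (1.0 + criterion.threshold) * ref.total_count
    fov_pass = {
        fid: now.fov_counts.get(fid, 0) >= (1.0 + criterion.threshold) * ref.fov_counts.get(fid, 0)
        for fid in now.fov_counts
    }
    return CriterionResult(now.total_count >= need and need > 0, fov_pass)


def _fraction_rule(history, ref, per_cell_pass, fraction):
    """Evaluate a per-cell predicate over cells present now and at reference."""
    now = history[-1]
    passes: dict[int, list[bool]] = {}
    for key, vals in now.cell_fluor.items():
        if ref is not None and key not in ref.cell_fluor:
            continue
        ok = per_cell_pass(key, vals, ref.cell_fluor[key] if ref is not None else None)
        passes.setdefault(key[0], []).append(ok)
    all_flags = [ok for flags in passes.values() for ok in flags]
    if not all_flags:
        return CriterionResult(False, {}, "no cells present at both timepoints")
    fov_pass = {
        fid: (sum(flags) / len(flags)) >= fraction for fid, flags in passes.items()
    }
    met = (sum(all_flags) / len(all_flags)) >= fraction
    return CriterionResult(met, fov_pass)


@register_criterion("fluorescence")
def _fluor_rule(criterion, history, ref, background, phase_start_idx):
    if ref is None:
        return CriterionResult(False, {}, "no reference cycle yet")

    def cell_ok(key, now_vals, ref_vals):
        raw_now, _ = now_vals
        raw_ref, _ = ref_vals
        return (raw_now - raw_ref) >= criterion.threshold * raw_ref

    return _fraction_rule(history, ref, cell_ok, criterion.fraction)


@register_criterion("fluorescence_over_background")
def _fluor_bg_rule(criterion, history, ref, background, phase_start_idx):
    if ref is None:
        return CriterionResult(False, {}, "no reference cycle yet")
    if background is None or background <= 0:
        return CriterionResult(False, {}, "no autofluorescence estimate yet")

    def cell_ok(key, now_vals, ref_vals):
        _, sub_now = now_vals
        _, sub_ref = ref_vals
        return (sub_now - sub_ref) >= criterion.threshold * background

    return _fraction_rule(history, ref, cell_ok, criterion.fraction)


@register_criterion("steadiness")
def _steadiness_rule(criterion, history, ref, background, phase_start_idx):
    # slope and level use the background-subtracted signal: autofluorescence
    # would otherwise inflate the level and mask a still-rising weak signal
    if len(history) < 5 or len(history) - phase_start_idx < 5:
        return CriterionResult(False, {}, "fewer than 5 timepoints in this phase")
    window = history[-5:]
    times = np.array([c.t_min for c in window])
    passes: dict[int, list[bool]] = {}
    for key, (_, sub_now) in history[-1].cell_fluor.items():
        series = [c.cell_fluor.get(key) for c in window]
        if any(s is None for s in series):
            continue
        values = np.array([s[1] for s in series])
        slope = float(np.polynomial.polynomial.polyfit(times, values, 1)[1])
        tol = criterion.epsilon * max(abs(sub_now), 1e-9)
        passes.setdefault(key[0], []).append(abs(slope) <= tol)
    all_flags = [ok for flags in passes.values() for ok in flags]
    if not all_flags:
        return CriterionResult(False, {}, "no cell has 5 consecutive timepoints")
    fov_pass = {fid: (sum(f) / len(f)) >= criterion.fraction for fid, f in passes.items()}
    return CriterionResult(sum(all_flags) / len(all_flags) >= criterion.fraction, fov_pass)


@register_criterion("elapsed")
def _elapsed_rule(criterion, history, ref, background, phase_start_idx):
    """Fixed-time phase: met once the phase has lasted ``threshold`` minutes.

    Models conventional (open-loop) experiments where media changes happen
    at operator-chosen times; all FOVs pass together.
    """
    start = history[phase_start_idx]
    now = history[-1]
    met = (now.t_min - start.t_min) >= criterion.threshold
    return CriterionResult(met, {fid: met for fid in now.fov_counts})


@register_criterion("doublings")
def _doublings_rule(criterion, history, ref, background, phase_start_idx):
    start = history[phase_start_idx]
    now = history[-1]
    factor = 2.0**criterion.threshold
    fov_pass = {
        fid: now.fov_counts.get(fid, 0) >= factor * start.fov_counts.get(fid, 0)
        for fid in now.fov_counts
    }
    return CriterionResult(
        start.total_count > 0 and now.total_count >= factor * start.total_count, fov_pass
    )


def evaluate_criterion(
    criterion: Criterion,
    history: Sequence[CycleData],
    reference: str = "phase_start",
    phase_start_idx: int = 0,
    background_level: float | None = None,
) -> CriterionResult:
    """Evaluate a stop criterion on the measurement history.

    Insufficient history (no cycles yet, no reference, fewer than 5 points
    for steadiness) yields "not met" rather than an error.  The result also
    carries a per-FOV pass map used by the FOV-dropping policies.
    """
    if len(history) == 0:
        return CriterionResult(False, {}, "no data yet")
    try:
        rule = _CRITERIA[criterion.name]
    except KeyError:
        raise KeyError(
            f"unknown criterion {criterion.name!r}; registered: {sorted(_CRITERIA)}"
        ) from None
    ref = _resolve_reference(history, reference, phase_start_idx)
    return rule(criterion, history, ref, background_level, phase_start_idx)


# --------------------------------------------------------------------------
# protocol I/O


def _criterion_from_dict(d: Mapping) -> Criterion:
    return Criterion(
        name=d["name"],
        fraction=float(d.get("fraction", 0.5)),
        threshold=float(d.get("threshold", 0.25)),
        epsilon=float(d.get("epsilon", STEADINESS_EPSILON)),
    )


def load_protocol(source: str | Path | Mapping) -> ExperimentProtocol:
    """Load an experiment protocol from a YAML/JSON file or a mapping."""
    if isinstance(source, Mapping):
        d = dict(source)
    else:
        text = Path(source).read_text()
        d = yaml.safe_load(text)
    phases = tuple(
        Phase(
            name=p.get("name", f"phase{i + 1}"),
            medium=p["medium"],
            criterion=_criterion_from_dict(p["criterion"]),
            reference=p.get("reference", p["criterion"].get("reference", "phase_start")),
            timeout_min=float(p.get("timeout_min", 600.0)),
            fov_policy=p.get("fov_policy", "keep_all"),
        )
        for i, p in enumerate(d["phases"])
    )
    channels = tuple(
        Channel(
            name=c["name"],
            filter_slot=int(c.get("filter_slot", i)),
            exposure_ms=float(c.get("exposure_ms", 75.0)),
        )
        for i, c in enumerate(d.get("channels", [{"name": "phase", "exposure_ms": 10.0}]))
    )
    n_af = d.get("n_af", "all")
    return ExperimentProtocol(
        phases=phases,
        channels=channels,
        n_af=n_af if n_af == "all" else int(n_af),
        period_min=(float(d["period_min"]) if d.get("period_min") is not None else None),
        seed=int(d.get("seed", 0)),
    )


def bundled_protocol(name: str) -> ExperimentProtocol:
    """Load a protocol shipped with the package.

    Available: ``maturation`` (adaptive chase), ``memory`` (double
    induction with FOV dropping), ``conventional_maturation`` (open-loop
    fixed-time chase).
    """
    ref = resources.files("cytoloop").joinpath(f"protocols/{name}.yaml")
    return load_protocol(yaml.safe_load(ref.read_text()))


# --------------------------------------------------------------------------
# the engine


@dataclass
class PhaseInterval:
    name: str
    medium: str
    start_min: float
    end_min: float

    @property
    def duration_min(self) -> float:
        return self.end_min - self.start_min


@dataclass
class ExperimentResult:
    """Everything an experiment produced."""

    status: str  # completed | timeout | no_valid_fovs
    trajectories: list[CellTrajectory]
    phase_intervals: list[PhaseInterval]
    retained_fov_history: list[list[int]]
    period_history_s: list[float]
    background_level: float | None
    n_cycles: int
    elapsed_min: float
    notification: dict
    events: list[dict] = field(default_factory=list)


def _default_notify(payload: dict) -> None:
    logger.info("experiment finished: %s", json.dumps(payload))


def run_experiment(
    protocol: ExperimentProtocol,
    microscope: VirtualMicroscope,
    fovs: Sequence[FieldOfView],
    seg_params: SegmentationParams | None = None,
    notify: Callable[[dict], None] | None = None,
    max_cycles: int = 5000,
    frame_hook: Callable[[int, str, int, float, np.ndarray], None] | None = None,
    mask_hook: Callable[[int, int, float, np.ndarray], None] | None = None,
) -> ExperimentResult:
    """Run a closed-loop experiment against a (virtual) microscope.

    Visits ``fovs`` in the given route order each cycle, processes images
    in the loop, evaluates the current phase's criterion, switches media /
    drops FOVs / re-plans the period per the protocol, and fires the
    notification callback exactly once at termination.

    The first channel whose name starts with "phase" drives segmentation;
    the first fluorescence channel supplies the per-cell intensities.
    ``frame_hook(fov_id, channel_name, frame_index, t_min, image)`` is
    called for every acquired image (e.g. to record raw frames to disk
    for later replay).
    """
    seg_params = seg_params or SegmentationParams()
    notify = notify or _default_notify
    channels = list(protocol.channels)
    phase_ch = next((c for c in channels if c.name.lower().startswith("phase")), channels[0])
    fluor_ch = next((c for c in channels if not c.name.lower().startswith("phase")), None)

    events: list[dict] = []

    def log_event(kind: str, **data):
        events.append({"event": kind, "clock_min": microscope.clock_s / 60.0, **data})

    def finish(status: str, history, intervals, retained_hist, periods, bg, n_cycles):
        trajs: list[CellTrajectory] = []
        next_gid = 1
        for fid in sorted(trackers):
            for tr in trackers[fid].trajectories.values():
                tr.cell_id = next_gid
                next_gid += 1
                trajs.append(tr)
        payload = {
            "status": status,
            "elapsed_min": microscope.clock_s / 60.0,
            "n_cells": history[-1].total_count if history else 0,
            "message": f"experiment ended with status {status!r} "
            f"after {n_cycles} cycles ({microscope.clock_s / 60.0:.1f} min)",
        }
        notify(payload)
        log_event("notification", **payload)
        return ExperimentResult(
            status=status,
            trajectories=trajs,
            phase_intervals=intervals,
            retained_fov_history=retained_hist,
            period_history_s=periods,
            background_level=bg,
            n_cycles=n_cycles,
            elapsed_min=microscope.clock_s / 60.0,
            notification=payload,
            events=events,
        )

    active = [f for f in fovs if f.retained]
    trackers: dict[int, Tracker] = {f.fov_id: Tracker(fov_id=f.fov_id) for f in active}
    if not active:
        return finish("no_valid_fovs", [], [], [], [], None, 0)

    model = microscope.latency
    eff_n_af = len(active) if protocol.n_af == "all" else min(int(protocol.n_af), len(active))
    period_s = min_resolution_adaptive(model, active, channels, eff_n_af)
    if protocol.period_min is not None:
        period_s = max(period_s, protocol.period_min * 60.0)

    history: list[CycleData] = []
    intervals: list[PhaseInterval] = []
    retained_hist: list[list[int]] = [[f.fov_id for f in active]]
    periods: list[float] = [period_s]

    phase_idx = 0
    phase_start_idx = 0
    phase_start_min = microscope.clock_s / 60.0
    background_level: float | None = None
    inducing_media = {"galactose", "galactose+CHX"}

    microscope.set_medium(protocol.phases[0].medium)
    log_event("phase_start", phase=protocol.phases[0].name, medium=protocol.phases[0].medium)

    n_cycles = 0
    while n_cycles < max_cycles:
        phase = protocol.phases[phase_idx]
        cycle_start_s = microscope.clock_s
        t_min = cycle_start_s / 60.0
        fov_counts: dict[int, int] = {}
        cell_fluor: dict[tuple[int, int], tuple[float, float]] = {}
        for i, fov in enumerate(active):
            microscope.move_to(fov.x, fov.y, fov.z)
            if i < eff_n_af:
                microscope.autofocus()
            phase_img = None
            fluor_img = None
            for ch in channels:
                img = microscope.snap_channel(ch)
                if frame_hook is not None:
                    frame_hook(fov.fov_id, ch.name, n_cycles, t_min, img)
                if ch is phase_ch:
                    phase_img = img
                elif fluor_ch is not None and ch is fluor_ch:
                    fluor_img = img
            labels = segment(phase_img, seg_params)
            if mask_hook is not None:
                mask_hook(fov.fov_id, n_cycles, t_min, labels.labels)
            if fluor_img is None:
                fluor_img = np.zeros_like(phase_img)
            ids = trackers[fov.fov_id].add_frame(labels, fluor_img, t_min)
            microscope.clock_s += model.processing_per_fov()
            fov_counts[fov.fov_id] = labels.n_cells
            for label, cid in ids.items():
                rec = trackers[fov.fov_id].trajectories[cid].records[-1]
                cell_fluor[(fov.fov_id, cid)] = (rec.mean_fluor, rec.mean_fluor - rec.background)
        history.append(CycleData(t_min=t_min, fov_counts=fov_counts, cell_fluor=cell_fluor))
        n_cycles += 1

        result = evaluate_criterion(
            phase.criterion, history, phase.reference, phase_start_idx, background_level
        )
        log_event(
            "criterion",
            phase=phase.name,
            met=result.met,
            n_cells=history[-1].total_count,
            detail=result.detail,
        )
        now_min = microscope.clock_s / 60.0
        if result.met:
            intervals.append(
                PhaseInterval(phase.name, phase.medium, phase_start_min, now_min)
            )
            # estimate autofluorescence before the first inducing phase begins
            if background_level is None and (
                phase_idx + 1 < len(protocol.phases)
                and protocol.phases[phase_idx + 1].medium in inducing_media
            ):
                vals = [
                    sub for cyc in history[phase_start_idx:] for (_, sub) in cyc.cell_fluor.values()
                ]
                background_level = float(np.median(np.abs(vals))) if vals else None
                log_event("autofluorescence_estimate", level=background_level)
            if phase.fov_policy in ("drop_failing", "drop_failing_and_rescale"):
                keep = [f for f in active if result.fov_pass.get(f.fov_id, False)]
                dropped = [f.fov_id for f in active if f not in keep]
                if keep and dropped:
                    log_event("fovs_dropped", dropped=dropped, kept=[f.fov_id for f in keep])
                    if phase.fov_policy == "drop_failing_and_rescale":
                        new_period, keep = rescale_on_drop(
                            model, keep, channels, protocol.n_af
                        )
                        if protocol.period_min is not None:
                            new_period = max(new_period, protocol.period_min * 60.0)
                        period_s = new_period
                        log_event("period_rescaled", period_s=period_s)
                    active = keep
                    eff_n_af = (
                        len(active)
                        if protocol.n_af == "all"
                        else min(int(protocol.n_af), len(active))
                    )
                    retained_hist.append([f.fov_id for f in active])
                    periods.append(period_s)
            if phase_idx + 1 == len(protocol.phases):
                return finish(
                    "completed", history, intervals, retained_hist, periods,
                    background_level, n_cycles,
                )
            phase_idx += 1
            phase_start_idx = len(history)
            phase_start_min = now_min
            microscope.set_medium(protocol.phases[phase_idx].medium)
            log_event(
                "phase_start",
                phase=protocol.phases[phase_idx].name,
                medium=protocol.phases[phase_idx].medium,
            )
        elif now_min - phase_start_min >= phase.timeout_min:
            intervals.append(PhaseInterval(phase.name, phase.medium, phase_start_min, now_min))
            log_event("timeout", phase=phase.name)
            return finish(
                "timeout", history, intervals, retained_hist, periods,
                background_level, n_cycles,
            )
        microscope.wait_until(cycle_start_s + period_s)

    intervals.append(
        PhaseInterval(
            protocol.phases[phase_idx].name,
            protocol.phases[phase_idx].medium,
            phase_start_min,
            microscope.clock_s / 60.0,
        )
    )
    log_event("max_cycles_reached")
    return finish(
        "timeout", history, intervals, retained_hist, periods, background_level, n_cycles
    )
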