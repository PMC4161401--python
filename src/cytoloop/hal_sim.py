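"""Hardware abstraction and virtual microscope.

The control engine talks to hardware through a small contract — stage,
focus drive, filter wheel, camera, media inlets and a clock — implemented
here by a virtual microscope over a simulated budding-yeast population
with galactose-inducible fluorescent-protein expression.

Biology model (per cell):

* Division is a pure-birth (Yule) process: each cell divides with rate
  ``ln 2 / doubling_time``, so the expected population doubles exactly once
  per doubling time.  A daughter buds tangent to its mother at a random
  angle, and the immature/mature fluorophore pools split between mother and
  daughter in proportion to cell volume.
* In galactose, transcription switches on after an induction delay — the
  configured naive delay the first time, a configured fraction of it on
  re-induction (transcriptional memory).  While on, the immature pool
  accrues at the transcription rate.  Glucose and raffinose keep
  transcription off (and reset the delay so memory applies next time).
* Immature fluorophore matures into the fluorescent form at rate ``a``
  (half-time ``ln 2 / a``); cycloheximide (CHX) blocks translation, which
  halts both production and division, so under galactose + CHX the total
  immature + mature pool of a cell is exactly conserved while mass moves
  from immature to mature.  No degradation or photobleaching is modeled:
  fluorescence falls only by dilution through budding.

Imaging model: phase contrast renders each cell as a dark interior ringed
by a bright halo on a mid-grey background (so interiors are fillable
regional minima), blurred with a Gaussian whose width grows with defocus
``|z - z_focus|``; fluorescence renders per-cell uniform intensity
proportional to the mature pool plus autofluorescence, scaled by exposure,
with per-cell multiplicative measurement noise.  Rendering never mutates
population state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage as ndi

from .autofocus import focus_search
from .fov_select import FieldOfView
from .latency import Channel, LatencyModel
from .segmentation import LabeledImage
from .tracking import CellRecord, CellTrajectory

__all__ = [
    "RAFFINOSE",
    "GLUCOSE",
    "GALACTOSE",
    "GALACTOSE_CHX",
    "MEDIA",
    "UnknownMediumError",
    "SimulationConfig",
    "VirtualCell",
    "VirtualPopulation",
    "advance_population",
    "render_phase",
    "render_fluorescence",
    "ground_truth_labels",
    "VirtualMicroscope",
    "simulate_chase",
]

RAFFINOSE = "raffinose"
GLUCOSE = "glucose"
GALACTOSE = "galactose"
GALACTOSE_CHX = "galactose+CHX"
MEDIA = (RAFFINOSE, GLUCOSE, GALACTOSE, GALACTOSE_CHX)

#: media in which the inducer is present
_INDUCING = {GALACTOSE, GALACTOSE_CHX}


class UnknownMediumError(ValueError):
    """Medium label is not one of the configured inlets."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the virtual yeast population.

    Times are minutes, lengths micrometres, fluorescence arbitrary units.
    Defaults describe GAL1-driven Venus expression in budding yeast:
    a ~90 min doubling time on raffinose-based medium, a ~12 min naive
    induction delay (cells pre-grown on raffinose are already derepressed,
    so galactose activation is fast) shortened six-fold on re-induction,
    and a maturation half-time of ~15 min (rate ln 2 / 15 per min).  The
    much longer induction delay of glucose-repressed cells is not modeled
    separately; protocols starting from glucose see the same naive delay.
    """

    doubling_time_min: float = 90.0
    induction_delay_naive_min: float = 12.0
    reinduction_factor: float = 1.0 / 6.0
    transcription_rate: float = 10.0  # a.u. immature protein per min
    maturation_rate: float = math.log(2.0) / 15.0  # 1/min
    autofluorescence: float = 50.0  # a.u.
    noise_cv: float = 0.10
    seed: int = 0
    chamber_um: tuple[float, float] = (3000.0, 3000.0)
    r_min_um: float = 2.0
    r_max_um: float = 3.5
    motion_sd_um: float = 0.02  # random-walk scale per sqrt(minute)
    perfusion_lag_min: float = 0.0
    focus_plane: tuple[float, float, float] = (0.0, 0.0, 0.0)  # z = a + b x + c y
    max_population: int = 10_000  # chamber saturation: division halts at cap

    def __post_init__(self):
        if not (0.0 <= self.noise_cv < 1.0):
            raise ValueError("noise_cv must lie in [0, 1)")
        for name in (
            "doubling_time_min",
            "induction_delay_naive_min",
            "transcription_rate",
            "maturation_rate",
            "autofluorescence",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def z_focus(self, x: float, y: float) -> float:
        a, b, c = self.focus_plane
        return a + b * x + c * y


@dataclass
class VirtualCell:
    """One simulated cell."""

    cell_id: int
    x: float
    y: float
    radius: float
    age_min: float = 0.0
    immature: float = 0.0
    mature: float = 0.0
    transcribing: bool = False
    induced_before: bool = False
    delay_remaining_min: float | None = None
    mother_id: int | None = None

    @property
    def volume(self) -> float:
        return self.radius**3


@dataclass
class VirtualPopulation:
    """Simulator state: the cells, the clock and the random stream."""

    config: SimulationConfig
    cells: list[VirtualCell] = field(default_factory=list)
    time_min: float = 0.0
    next_id: int = 1
    rng: np.random.Generator = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.rng is None:
            self.rng = np.random.default_rng(self.config.seed)

    @classmethod
    def seeded(
        cls,
        config: SimulationConfig,
        n_cells: int,
        clustered: bool = False,
        min_gap_um: float = 0.5,
    ) -> "VirtualPopulation":
        """Scatter ``n_cells`` uniformly (or in loose clusters) in the chamber.

        Placement is rejection-sampled so cell bodies never interpenetrate
        (at least ``min_gap_um`` between membranes), as for trapped yeast
        in a monolayer.
        """
        pop = cls(config=config)
        w, h = config.chamber_um
        rng = pop.rng
        centers = None
        if clustered:
            n_clusters = max(1, n_cells // 6)
            centers = rng.uniform((0, 0), (w, h), size=(n_clusters, 2))
        placed: list[tuple[float, float, float]] = []
        for _ in range(n_cells):
            radius = float(rng.uniform(config.r_min_um, config.r_max_um))
            for _attempt in range(200):
                if centers is not None:
                    cx, cy = centers[rng.integers(len(centers))]
                    x = float(np.clip(cx + rng.normal(0, 8.0), 0, w))
                    y = float(np.clip(cy + rng.normal(0, 8.0), 0, h))
                else:
                    x, y = float(rng.uniform(0, w)), float(rng.uniform(0, h))
                if all(
                    math.hypot(x - px, y - py) >= radius + pr + min_gap_um
                    for px, py, pr in placed
                ):
                    break
            placed.append((x, y, radius))
            pop.cells.append(
                VirtualCell(cell_id=pop.next_id, x=x, y=y, radius=radius)
            )
            pop.next_id += 1
        return pop

    def count(self) -> int:
        return len(self.cells)


def _update_pools(cell: VirtualCell, dt: float, a: float, producing: bool, k: float) -> None:
    """Exact constant-coefficient update of the two-pool maturation ODE.

    dI/dt = k*producing - a I ;  dM/dt = a I.  The transfer I -> M conserves
    I + M when production is off.
    """
    if a <= 0:
        if producing:
            cell.immature += k * dt
        return
    decay = math.exp(-a * dt)
    i0 = cell.immature
    if producing:
        cell.immature = i0 * decay + (k / a) * (1.0 - decay)
        cell.mature += i0 * (1.0 - decay) + k * (dt - (1.0 - decay) / a)
    else:
        cell.immature = i0 * decay
        cell.mature += i0 * (1.0 - decay)


def _bud_site(
    pop: VirtualPopulation, mother: VirtualCell, r_d: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Pick a bud position tangent to the mother.

    Buds grow into free space: up to 12 random angles are tried and the
    first spot whose disc does not interpenetrate a neighbour is taken;
    failing that, the least-crowded angle wins.  Only cells within one
    bud-reach of the mother are checked.
    """
    cfg = pop.config
    w, h = cfg.chamber_um
    reach = mother.radius + 2 * r_d + cfg.r_max_um
    neighbours = [
        c
        for c in pop.cells
        if c is not mother and abs(c.x - mother.x) < reach and abs(c.y - mother.y) < reach
    ]
    best: tuple[float, float, float] | None = None  # (overlap, x, y)
    for _ in range(12):
        theta = float(rng.uniform(0, 2 * math.pi))
        bx = float(np.clip(mother.x + (mother.radius + r_d) * math.cos(theta), 0, w))
        by = float(np.clip(mother.y + (mother.radius + r_d) * math.sin(theta), 0, h))
        crowd = 0.0
        for c in neighbours:
            gap = math.hypot(bx - c.x, by - c.y) - (r_d + c.radius)
            if gap < 0:
                crowd += -gap
        if crowd == 0.0:
            return bx, by
        if best is None or crowd < best[0]:
            best = (crowd, bx, by)
    assert best is not None
    return best[1], best[2]


def advance_population(
    pop: VirtualPopulation, dt_min: float, medium: str, substep_min: float = 0.5
) -> VirtualPopulation:
    """Advance the biology by ``dt_min`` minutes under the given medium.

    Mutates and returns ``pop``.  Division, induction-delay countdown and
    pool kinetics are integrated in substeps; pool updates are exact within
    each substep, and the per-substep division probability is chosen so the
    expected count grows as ``2^(t / doubling_time)`` exactly.
    """
    if dt_min <= 0:
        raise ValueError("dt_min must be > 0")
    if medium not in MEDIA:
        raise UnknownMediumError(f"unknown medium {medium!r}; expected one of {MEDIA}")
    cfg = pop.config
    chx = medium == GALACTOSE_CHX
    inducing = medium in _INDUCING
    growth_rate = math.log(2.0) / cfg.doubling_time_min
    a = cfg.maturation_rate
    rng = pop.rng

    remaining = dt_min
    while remaining > 1e-12:
        dt = min(substep_min, remaining)
        remaining -= dt
        p_div = 0.0 if chx else min(1.0, math.exp(growth_rate * dt) - 1.0)
        daughters: list[VirtualCell] = []
        for cell in pop.cells:
            # transcription state machine
            if inducing and not chx:
                if not cell.transcribing:
                    if cell.delay_remaining_min is None:
                        naive = cfg.induction_delay_naive_min
                        cell.delay_remaining_min = (
                            naive * cfg.reinduction_factor if cell.induced_before else naive
                        )
                    cell.delay_remaining_min -= dt
                    if cell.delay_remaining_min <= 0:
                        cell.transcribing = True
                        cell.induced_before = True
                        cell.delay_remaining_min = None
            elif not inducing:
                cell.transcribing = False
                cell.delay_remaining_min = None

            producing = cell.transcribing and inducing and not chx
            _update_pools(cell, dt, a, producing, cfg.transcription_rate)
            cell.age_min += dt
            if cfg.motion_sd_um > 0:
                step = cfg.motion_sd_um * math.sqrt(dt)
                cell.x = float(np.clip(cell.x + rng.normal(0, step), 0, cfg.chamber_um[0]))
                cell.y = float(np.clip(cell.y + rng.normal(0, step), 0, cfg.chamber_um[1]))

            if (
                p_div > 0
                and len(pop.cells) + len(daughters) < cfg.max_population
                and rng.random() < p_div
            ):
                r_d = float(rng.uniform(cfg.r_min_um, cfg.r_max_um))
                bx, by = _bud_site(pop, cell, r_d, rng)
                d = VirtualCell(
                    cell_id=pop.next_id,
                    x=bx,
                    y=by,
                    radius=r_d,
                    transcribing=cell.transcribing,
                    induced_before=cell.induced_before,
                    delay_remaining_min=cell.delay_remaining_min,
                    mother_id=cell.cell_id,
                )
                pop.next_id += 1
                frac_d = d.volume / (cell.volume + d.volume)
                d.immature, d.mature = cell.immature * frac_d, cell.mature * frac_d
                cell.immature *= 1.0 - frac_d
                cell.mature *= 1.0 - frac_d
                daughters.append(d)
        pop.cells.extend(daughters)
        pop.time_min += dt
    return pop


# --------------------------------------------------------------------------
# rendering

#: phase-contrast grey levels (fraction of full scale)
_PHASE_BACKGROUND = 0.40
_PHASE_INTERIOR = 0.15
_PHASE_RIM = 0.95
_RIM_WIDTH_UM = 0.6
#: defocus blur: sigma_px = base + slope * |z - z_focus|
_BLUR_BASE_PX = 0.6
_BLUR_PER_UM = 0.9

DEFAULT_PIXEL_UM = 0.205  # 6.45 um sensor pixels, 63x objective, 2x2 binning


def _cells_in_fov(
    pop: VirtualPopulation, fov: FieldOfView, shape: tuple[int, int], pixel_um: float
) -> list[tuple[VirtualCell, float, float]]:
    """Cells whose disc intersects the FOV, with centre pixel coordinates."""
    h, w = shape
    x0 = fov.x - w * pixel_um / 2.0
    y0 = fov.y - h * pixel_um / 2.0
    out = []
    for cell in pop.cells:
        col = (cell.x - x0) / pixel_um
        row = (cell.y - y0) / pixel_um
        r_px = cell.radius / pixel_um
        if -r_px <= col < w + r_px and -r_px <= row < h + r_px:
            out.append((cell, row, col))
    # raster order of centres keeps ground-truth labels deterministic
    out.sort(key=lambda t: (t[1], t[2]))
    return out


def render_phase(
    pop: VirtualPopulation,
    fov: FieldOfView,
    z: float,
    shape: tuple[int, int] = (256, 256),
    pixel_um: float = DEFAULT_PIXEL_UM,
) -> np.ndarray:
    """Phase-contrast render of the FOV at stage height ``z``.

    Cells are dark interiors with bright rims on a mid-grey background;
    the whole frame is blurred with sigma growing linearly in the defocus
    ``|z - z_focus(x, y)|``.  Pure function of population state.
    """
    h, w = shape
    img = np.full(shape, _PHASE_BACKGROUND, dtype=np.float64)
    rows, cols = np.mgrid[0:h, 0:w]
    cells = _cells_in_fov(pop, fov, shape, pixel_um)

    def patches():
        for cell, crow, ccol in cells:
            r_px = cell.radius / pixel_um
            rim_px = max(1.5, _RIM_WIDTH_UM / pixel_um)
            lo_r = max(0, int(crow - r_px - rim_px - 2))
            hi_r = min(h, int(crow + r_px + rim_px + 3))
            lo_c = max(0, int(ccol - r_px - rim_px - 2))
            hi_c = min(w, int(ccol + r_px + rim_px + 3))
            if lo_r >= hi_r or lo_c >= hi_c:
                continue
            d = np.hypot(
                rows[lo_r:hi_r, lo_c:hi_c] - crow, cols[lo_r:hi_r, lo_c:hi_c] - ccol
            )
            yield img[lo_r:hi_r, lo_c:hi_c], d, r_px, rim_px

    # interiors first, halos second: touching cells keep a bright ridge
    # between their interiors, as the overlapping halos do in phase contrast
    for patch, d, r_px, rim_px in patches():
        patch[d <= r_px - rim_px / 2] = _PHASE_INTERIOR
    for patch, d, r_px, rim_px in patches():
        patch[(d > r_px - rim_px / 2) & (d <= r_px + rim_px / 2)] = _PHASE_RIM
    sigma = _BLUR_BASE_PX + _BLUR_PER_UM * abs(z - pop.config.z_focus(fov.x, fov.y))
    return ndi.gaussian_filter(img, sigma=sigma, mode="nearest")


def ground_truth_labels(
    pop: VirtualPopulation,
    fov: FieldOfView,
    shape: tuple[int, int] = (256, 256),
    pixel_um: float = DEFAULT_PIXEL_UM,
) -> tuple[LabeledImage, dict[int, int]]:
    """True label mask of the FOV plus {label -> simulator cell id}."""
    h, w = shape
    lab = np.zeros(shape, dtype=np.int32)
    rows, cols = np.mgrid[0:h, 0:w]
    ids: dict[int, int] = {}
    k = 0
    for cell, crow, ccol in _cells_in_fov(pop, fov, shape, pixel_um):
        r_px = cell.radius / pixel_um
        d2 = (rows - crow) ** 2 + (cols - ccol) ** 2
        inside = d2 <= r_px**2
        if not inside.any():
            continue
        k += 1
        lab[inside] = k  # later (lower) cells overwrite at contacts
        ids[k] = cell.cell_id
    return LabeledImage(labels=lab, n_cells=k), ids


_FLUOR_BACKGROUND = 5.0  # dark level, a.u.
_REFERENCE_EXPOSURE_MS = 75.0


def render_fluorescence(
    pop: VirtualPopulation,
    fov: FieldOfView,
    z: float,
    exposure_ms: float = 75.0,
    shape: tuple[int, int] = (256, 256),
    pixel_um: float = DEFAULT_PIXEL_UM,
    noise_key: int | None = None,
) -> np.ndarray:
    """Fluorescence render: per-cell intensity from the mature pool.

    Pixel value inside a cell is ``(mature + autofluorescence) * exposure /
    75 ms``, multiplied by a per-cell noise factor ``1 + N(0, noise_cv)``;
    the background is a constant dark level.  ``noise_key`` seeds the noise
    stream (together with the config seed) so identical command sequences
    reproduce identical images without mutating population state.
    """
    if exposure_ms <= 0:
        raise ValueError("exposure must be > 0")
    h, w = shape
    scale = exposure_ms / _REFERENCE_EXPOSURE_MS
    img = np.full(shape, _FLUOR_BACKGROUND * scale, dtype=np.float64)
    key = noise_key if noise_key is not None else int(round(pop.time_min * 1000))
    rng = np.random.default_rng((pop.config.seed, 0x5EED, key & 0x7FFFFFFF))
    rows, cols = np.mgrid[0:h, 0:w]
    for cell, crow, ccol in _cells_in_fov(pop, fov, shape, pixel_um):
        noise = 1.0 + rng.normal(0.0, pop.config.noise_cv) if pop.config.noise_cv > 0 else 1.0
        value = (cell.mature + pop.config.autofluorescence) * scale * max(0.0, noise)
        r_px = cell.radius / pixel_um
        d2 = (rows - crow) ** 2 + (cols - ccol) ** 2
        img[d2 <= r_px**2] = value
    return img


# --------------------------------------------------------------------------
# the hardware contract implementation


class VirtualMicroscope:
    """Virtual implementation of the hardware contract.

    Every commanded action advances the wall clock by the latency model's
    cost for that action; biology is synchronized to the clock at medium
    changes and explicit waits (intra-cycle latencies are short relative to
    the kinetics, so cells are effectively frozen while a cycle's images
    are snapped).  Snapping an image advances only the clock.
    """

    def __init__(
        self,
        population: VirtualPopulation,
        latency_model: LatencyModel | None = None,
        medium: str = RAFFINOSE,
        image_shape: tuple[int, int] = (256, 256),
        pixel_um: float = DEFAULT_PIXEL_UM,
    ):
        self.population = population
        self.latency = latency_model or LatencyModel()
        self.x = 0.0
        self.y = 0.0
        self.z = 0.0
        self.filter_slot = 0
        self.medium = medium
        self.clock_s = 0.0
        self.image_shape = image_shape
        self.pixel_um = pixel_um
        self._pending_medium: tuple[float, str] | None = None  # (effective clock_s, label)
        self._snap_counter = 0

    # -- clock / biology sync ------------------------------------------------

    def _sync_population(self) -> None:
        """Advance the biology up to the current clock."""
        target_min = self.clock_s / 60.0
        if self._pending_medium is not None:
            t_eff = self._pending_medium[0] / 60.0
            if target_min >= t_eff:
                if t_eff > self.population.time_min:
                    advance_population(self.population, t_eff - self.population.time_min, self.medium)
                self.medium = self._pending_medium[1]
                self._pending_medium = None
        if target_min > self.population.time_min + 1e-9:
            advance_population(self.population, target_min - self.population.time_min, self.medium)

    def wait_until(self, clock_s: float) -> None:
        """Idle (biology keeps running) until the given wall-clock time."""
        if clock_s > self.clock_s:
            self.clock_s = clock_s
        self._sync_population()

    def wait(self, seconds: float) -> None:
        self.wait_until(self.clock_s + seconds)

    # -- stage / filters / media ---------------------------------------------

    def move_to(self, x: float, y: float, z: float | None = None) -> None:
        dist = math.hypot(x - self.x, y - self.y)
        self.clock_s += self.latency.t_mot(dist)
        self.x, self.y = x, y
        if z is not None:
            self.z = z

    def move_z(self, z: float) -> None:
        self.z = z  # focus-drive moves are folded into t_AF accounting

    def set_filter(self, slot: int) -> None:
        self.clock_s += self.latency.t_filt(abs(slot - self.filter_slot))
        self.filter_slot = slot

    def set_medium(self, label: str) -> None:
        """Switch the media inlet (takes effect after the perfusion lag)."""
        if label not in MEDIA:
            raise UnknownMediumError(f"unknown medium {label!r}; expected one of {MEDIA}")
        self._sync_population()
        lag_s = self.population.config.perfusion_lag_min * 60.0
        if lag_s > 0:
            self._pending_medium = (self.clock_s + lag_s, label)
        else:
            self.medium = label

    # -- camera ----------------------------------------------------------------

    def current_fov(self) -> FieldOfView:
        return FieldOfView(x=self.x, y=self.y, z=self.z)

    def snap_phase(self, exposure_ms: float = 10.0) -> np.ndarray:
        self.clock_s += exposure_ms / 1000.0
        return render_phase(
            self.population, self.current_fov(), self.z, self.image_shape, self.pixel_um
        )

    def snap_fluorescence(self, exposure_ms: float = 75.0) -> np.ndarray:
        self.clock_s += exposure_ms / 1000.0
        self._snap_counter += 1
        return render_fluorescence(
            self.population,
            self.current_fov(),
            self.z,
            exposure_ms,
            self.image_shape,
            self.pixel_um,
            noise_key=self._snap_counter,
        )

    def snap_channel(self, channel: Channel) -> np.ndarray:
        """Set the channel's filter and snap with its exposure."""
        self.set_filter(channel.filter_slot)
        if channel.name.lower().startswith("phase"):
            return self.snap_phase(channel.exposure_ms)
        return self.snap_fluorescence(channel.exposure_ms)

    def autofocus(self) -> float:
        """Software autofocus at the current position; costs t_AF."""

        def source(z: float) -> np.ndarray:
            return render_phase(
                self.population, self.current_fov(), z, self.image_shape, self.pixel_um
            )

        z_star = focus_search(source, self.z)
        self.clock_s += self.latency.t_af()
        self.z = z_star
        return z_star

    def ground_truth(self) -> tuple[LabeledImage, dict[int, int]]:
        """True labels of the current FOV (testing hook, no clock cost)."""
        return ground_truth_labels(
            self.population, self.current_fov(), self.image_shape, self.pixel_um
        )


# --------------------------------------------------------------------------
# trajectory-level experiment simulators


def simulate_chase(
    half_time_min: float,
    n_cells: int = 150,
    dt_min: float = 5.0,
    production_min: float = 30.0,
    chase_min: float = 255.0,
    noise_cv: float = 0.10,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> tuple[list[CellTrajectory], float]:
    """Simulate a cycloheximide-chase maturation experiment.

    Cells produce immature fluorophore in galactose for ``production_min``
    minutes (the induction delay is skipped: cells start transcribing), then
    translation is blocked and the population is sampled every ``dt_min``
    minutes for ``chase_min`` minutes.  Each sample records per-cell mean
    fluorescence ``(mature + autofluorescence) * (1 + N(0, noise_cv))``
    with the autofluorescence level as the background field.

    Returns ``(trajectories, t_chx_min)`` where times in the records are
    absolute and ``t_chx_min`` is the translation-block time (the fitting
    time origin).
    """
    cfg = config or SimulationConfig(
        maturation_rate=math.log(2.0) / half_time_min,
        noise_cv=noise_cv,
        seed=seed,
    )
    if config is not None:
        cfg = replace(cfg, maturation_rate=math.log(2.0) / half_time_min, noise_cv=noise_cv, seed=seed)
    pop = VirtualPopulation.seeded(cfg, n_cells)
    for cell in pop.cells:
        cell.transcribing = True  # induction delay already elapsed
        cell.induced_before = True
    meas_rng = np.random.default_rng((seed, 0xC4A5E))

    trajectories: dict[int, CellTrajectory] = {}
    frame = 0

    def record_all() -> None:
        nonlocal frame
        for cell in pop.cells:
            tr = trajectories.get(cell.cell_id)
            if tr is None:
                tr = CellTrajectory(cell_id=cell.cell_id, fov_id=0, mother_id=cell.mother_id)
                trajectories[cell.cell_id] = tr
            noise = 1.0 + meas_rng.normal(0.0, noise_cv) if noise_cv > 0 else 1.0
            tr.records.append(
                CellRecord(
                    t_min=pop.time_min,
                    frame=frame,
                    area_px=max(1, int(math.pi * (cell.radius / DEFAULT_PIXEL_UM) ** 2)),
                    mean_fluor=(cell.mature + cfg.autofluorescence) * max(0.0, noise),
                    background=cfg.autofluorescence,
                    fov_id=0,
                )
            )
        frame += 1

    record_all()
    n_prod = int(round(production_min / dt_min))
    for _ in range(n_prod):
        advance_population(pop, dt_min, GALACTOSE)
        record_all()
    t_chx = pop.time_min
    n_chase = int(round(chase_min / dt_min))
    for _ in range(n_chase):
        advance_population(pop, dt_min, GALACTOSE_CHX)
        record_all()
    return list(trajectories.values()), t_chx
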