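"""Shared fixtures: synthetic images and small virtual-microscope rigs."""

from __future__ import annotations

import numpy as np
import pytest

import cytoloop as cl
from cytoloop.fov_select import FieldOfView, plan_scan, select_fovs
from cytoloop.hal_sim import DEFAULT_PIXEL_UM, ground_truth_labels


def make_ring_image(
    shape=(128, 128),
    centers=((64, 64),),
    interior_radius=10.0,
    rim_width=3.0,
    background=0.4,
    interior=0.15,
    rim=0.95,
):
    """Synthetic phase-contrast-like image: dark discs ringed by bright rims.

    ``interior_radius`` is the radius of the dark interior; the rim extends
    ``rim_width`` px beyond it.
    """
    img = np.full(shape, background, dtype=np.float64)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cr, cc in centers:
        d = np.hypot(rows - cr, cols - cc)
        img[(d > interior_radius) & (d <= interior_radius + rim_width)] = rim
        img[d <= interior_radius] = interior
    return img


def separated_population(n_cells=10, seed=2, chamber=52.0, spacing=9.5, margin=7.0):
    """Population of well-separated cells laid out inside one 256x256 FOV.

    A jittered grid keeps every cell at least ``margin`` um from the FOV
    edge so no disc is clipped by the image border.
    """
    cfg = cl.SimulationConfig(seed=seed, chamber_um=(chamber, chamber), motion_sd_um=0.0)
    pop = cl.VirtualPopulation(config=cfg)
    rng = np.random.default_rng(seed)
    per_row = max(1, int((chamber - 2 * margin) // spacing) + 1)
    assert n_cells <= per_row * per_row, "layout does not fit in the FOV"
    for i in range(n_cells):
        gx, gy = i % per_row, i // per_row
        pop.cells.append(
            cl.VirtualCell(
                cell_id=i + 1,
                x=margin + gx * spacing + rng.uniform(-1, 1),
                y=margin + gy * spacing + rng.uniform(-1, 1),
                radius=rng.uniform(2.0, 3.0),
            )
        )
    pop.next_id = n_cells + 1
    return pop


def center_fov():
    return FieldOfView(x=26.0, y=26.0, z=0.0, fov_id=0)


def experiment_rig(seed, doubling=45.0, delay=15.0, chamber=200.0, n_cells=30,
                   shape=(192, 192), n_fovs=2, max_cells=20):
    """Seed a small clustered chamber, scan it and select FOVs.

    ``max_cells`` caps the per-FOV count at selection; protocols whose
    criteria need room for several population doublings inside the FOV
    should start sparse (low ``max_cells``, larger ``shape``).
    """
    cfg = cl.SimulationConfig(
        seed=seed,
        chamber_um=(chamber, chamber),
        doubling_time_min=doubling,
        induction_delay_naive_min=delay,
    )
    pop = cl.VirtualPopulation.seeded(cfg, n_cells, clustered=True)
    scope = cl.VirtualMicroscope(pop, image_shape=shape, medium=cl.RAFFINOSE)
    plan = plan_scan(
        [(0, 0, 0), (chamber, 0, 0), (chamber, chamber, 0)],
        shape, DEFAULT_PIXEL_UM, magnification=1.0,
    )
    cands = [
        FieldOfView(x=f.x, y=f.y, z=f.z, fov_id=f.fov_id,
                    cell_count=ground_truth_labels(pop, f, shape)[0].n_cells)
        for f in plan.positions
    ]
    return scope, select_fovs(cands, n_fovs, max_cells=max_cells)


@pytest.fixture
def ten_cell_fov():
    """(population, fov) with 10 well-separated cells in view."""
    return separated_population(10), center_fov()
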