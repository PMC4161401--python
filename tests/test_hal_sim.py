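"""Virtual microscope: population kinetics, rendering, hardware contract."""

import math

import numpy as np
import pytest

import cytoloop as cl
from cytoloop.autofocus import contrast
from cytoloop.hal_sim import (
    GALACTOSE,
    GALACTOSE_CHX,
    GLUCOSE,
    RAFFINOSE,
    SimulationConfig,
    UnknownMediumError,
    VirtualCell,
    VirtualMicroscope,
    VirtualPopulation,
    advance_population,
    ground_truth_labels,
    render_fluorescence,
    render_phase,
    simulate_chase,
)
from cytoloop.latency import LatencyModel
from cytoloop.segmentation import segment

from conftest import center_fov, separated_population


class TestPopulationKinetics:
    def test_growth_doubles_in_one_doubling_time(self):
        """Pure-birth growth: expected count doubles per doubling time."""
        counts = []
        for seed in range(5):
            pop = VirtualPopulation.seeded(SimulationConfig(seed=seed), 100)
            advance_population(pop, 90.0, RAFFINOSE)
            counts.append(pop.count())
        mean = np.mean(counts)
        # binomial-scale sampling error around 200
        assert abs(mean - 200) < 3 * math.sqrt(200) / math.sqrt(5) + 5

    def test_unknown_medium_rejected(self):
        pop = VirtualPopulation.seeded(SimulationConfig(), 3)
        with pytest.raises(UnknownMediumError):
            advance_population(pop, 1.0, "lactose")

    def test_chx_conserves_total_pool(self):
        pop = VirtualPopulation.seeded(SimulationConfig(seed=1), 8)
        for c in pop.cells:
            c.immature, c.mature = 120.0, 30.0
        advance_population(pop, 75.0, GALACTOSE_CHX)
        assert pop.count() == 8  # no division under translation block
        for c in pop.cells:
            assert c.immature + c.mature == pytest.approx(150.0)
            assert c.immature >= 0 and c.mature >= 0

    def test_maturation_closed_form_under_chx(self):
        cfg = SimulationConfig(seed=2)
        pop = VirtualPopulation.seeded(cfg, 1)
        cell = pop.cells[0]
        cell.immature, cell.mature = 100.0, 5.0
        advance_population(pop, 40.0, GALACTOSE_CHX)
        expected = 5.0 + 100.0 * (1 - math.exp(-cfg.maturation_rate * 40.0))
        assert cell.mature == pytest.approx(expected, rel=1e-9)

    def test_induction_delay_then_production(self):
        cfg = SimulationConfig(seed=3, induction_delay_naive_min=30.0,
                               doubling_time_min=1e7, motion_sd_um=0.0)
        pop = VirtualPopulation.seeded(cfg, 4)
        advance_population(pop, 20.0, GALACTOSE)
        assert all(not c.transcribing for c in pop.cells)
        assert all(c.immature == 0 for c in pop.cells)
        advance_population(pop, 20.0, GALACTOSE)
        assert all(c.transcribing for c in pop.cells)
        assert all(c.immature > 0 for c in pop.cells)

    def test_reinduction_is_faster(self):
        cfg = SimulationConfig(seed=4, induction_delay_naive_min=36.0,
                               doubling_time_min=1e7, motion_sd_um=0.0)
        pop = VirtualPopulation.seeded(cfg, 4)
        advance_population(pop, 60.0, GALACTOSE)  # past naive delay: induced
        advance_population(pop, 30.0, GLUCOSE)  # repress (resets delay)
        for c in pop.cells:
            c.immature = c.mature = 0.0
        # re-induction delay = 36/6 = 6 min: production within 10 min
        advance_population(pop, 10.0, GALACTOSE)
        assert all(c.transcribing for c in pop.cells)
        assert all(c.immature > 0 for c in pop.cells)

    def test_glucose_keeps_transcription_off(self):
        pop = VirtualPopulation.seeded(SimulationConfig(seed=5, doubling_time_min=1e7), 3)
        advance_population(pop, 120.0, GLUCOSE)
        assert all(not c.transcribing and c.immature == 0 for c in pop.cells)

    def test_count_never_decreases_and_pools_nonnegative(self):
        pop = VirtualPopulation.seeded(SimulationConfig(seed=6, doubling_time_min=60.0), 20)
        for c in pop.cells:
            c.mature = 50.0
        last = pop.count()
        for medium in (RAFFINOSE, GALACTOSE, GLUCOSE, RAFFINOSE):
            advance_population(pop, 30.0, medium)
            assert pop.count() >= last
            last = pop.count()
            assert all(c.immature >= 0 and c.mature >= 0 for c in pop.cells)

    def test_determinism_same_seed(self):
        def run():
            pop = VirtualPopulation.seeded(SimulationConfig(seed=7), 30)
            advance_population(pop, 100.0, GALACTOSE)
            return [(c.cell_id, c.x, c.y, c.immature, c.mature) for c in pop.cells]

        assert run() == run()

    def test_budding_splits_pools_proportional_to_volume(self):
        cfg = SimulationConfig(seed=8, doubling_time_min=5.0, motion_sd_um=0.0)
        pop = VirtualPopulation.seeded(cfg, 1)
        mother = pop.cells[0]
        mother.mature = 90.0
        total_before = 90.0
        while pop.count() == 1:  # force one division
            advance_population(pop, 1.0, RAFFINOSE)
        assert sum(c.mature for c in pop.cells) == pytest.approx(total_before)
        daughter = pop.cells[1]
        assert daughter.mother_id == mother.cell_id
        ratio = daughter.mature / mother.mature
        assert ratio == pytest.approx(daughter.volume / mother.volume, rel=1e-9)


class TestRendering:
    def test_empty_fov_renders_background_only(self):
        pop = separated_population(0)
        img = render_phase(pop, center_fov(), 0.0, (128, 128))
        assert img.std() < 1e-9
        assert segment(img).n_cells == 0

    def test_separated_cells_segment_to_truth(self, ten_cell_fov):
        pop, fov = ten_cell_fov
        assert segment(render_phase(pop, fov, 0.0, (256, 256))).n_cells == 10

    def test_defocus_lowers_contrast(self, ten_cell_fov):
        pop, fov = ten_cell_fov
        c_focus = contrast(render_phase(pop, fov, 0.0, (256, 256))).C
        for dz in (-4.0, 4.0):
            assert contrast(render_phase(pop, fov, dz, (256, 256))).C < c_focus

    def test_fluorescence_zero_pool_reads_autofluorescence(self):
        pop = separated_population(5, seed=3)
        fov = center_fov()
        cfg = pop.config
        img = render_fluorescence(pop, fov, 0.0, 75.0, (256, 256), noise_key=1)
        gt, _ = ground_truth_labels(pop, fov, (256, 256))
        for k in range(1, gt.n_cells + 1):
            vals = img[gt.labels == k]
            # multiplicative noise at CV 10% around the autofluorescence level
            assert abs(vals.mean() - cfg.autofluorescence) < 4 * 0.1 * cfg.autofluorescence

    def test_fluorescence_linear_in_mature_pool(self):
        pop = separated_population(4, seed=4)
        pop.config = SimulationConfig(seed=4, chamber_um=(52.0, 52.0), noise_cv=0.0)
        fov = center_fov()
        gt, _ = ground_truth_labels(pop, fov, (256, 256))
        for c in pop.cells:
            c.mature = 100.0
        img1 = render_fluorescence(pop, fov, 0.0, 75.0, (256, 256), noise_key=1)
        for c in pop.cells:
            c.mature = 200.0
        img2 = render_fluorescence(pop, fov, 0.0, 75.0, (256, 256), noise_key=1)
        bg = pop.config.autofluorescence
        for k in range(1, gt.n_cells + 1):
            v1 = img1[gt.labels == k].mean() - bg
            v2 = img2[gt.labels == k].mean() - bg
            assert v2 == pytest.approx(2 * v1, rel=1e-9)

    def test_noise_free_render_is_exact(self):
        pop = separated_population(3, seed=5)
        pop.config = SimulationConfig(seed=5, chamber_um=(52.0, 52.0), noise_cv=0.0)
        for c in pop.cells:
            c.mature = 40.0
        fov = center_fov()
        img = render_fluorescence(pop, fov, 0.0, 75.0, (256, 256), noise_key=0)
        gt, _ = ground_truth_labels(pop, fov, (256, 256))
        for k in range(1, gt.n_cells + 1):
            assert np.allclose(img[gt.labels == k], 40.0 + pop.config.autofluorescence)

    def test_render_does_not_mutate_population(self, ten_cell_fov):
        pop, fov = ten_cell_fov
        before = [(c.x, c.y, c.immature, c.mature) for c in pop.cells]
        render_phase(pop, fov, 1.0, (128, 128))
        render_fluorescence(pop, fov, 1.0, 75.0, (128, 128), noise_key=3)
        assert [(c.x, c.y, c.immature, c.mature) for c in pop.cells] == before


class TestVirtualMicroscope:
    def test_clock_advances_per_latency_model(self):
        pop = VirtualPopulation.seeded(SimulationConfig(seed=0), 0)
        model = LatencyModel(t_af_coeffs=(4.0,), t_mot_coeffs=(0.0, 0.01),
                             t_filt_coeffs=(0.5,))
        scope = VirtualMicroscope(pop, model)
        scope.move_to(100.0, 0.0, 0.0)
        assert scope.clock_s == pytest.approx(1.0)  # 100 um at 10 ms/um
        scope.set_filter(2)
        assert scope.clock_s == pytest.approx(1.5)
        scope.snap_phase(exposure_ms=10)
        assert scope.clock_s == pytest.approx(1.51)
        scope.autofocus()
        assert scope.clock_s == pytest.approx(5.51)

    def test_clock_monotonic_over_command_sequence(self):
        pop = VirtualPopulation.seeded(SimulationConfig(seed=1), 5)
        scope = VirtualMicroscope(pop)
        last = scope.clock_s
        for cmd in range(20):
            scope.move_to(cmd * 10.0, 0.0)
            scope.snap_phase()
            scope.wait(5.0)
            assert scope.clock_s >= last
            last = scope.clock_s

    def test_wait_advances_biology(self):
        pop = VirtualPopulation.seeded(SimulationConfig(seed=2), 5)
        scope = VirtualMicroscope(pop, medium=RAFFINOSE)
        scope.wait(600.0)
        assert pop.time_min == pytest.approx(10.0)

    def test_perfusion_lag_delays_medium_change(self):
        cfg = SimulationConfig(seed=3, perfusion_lag_min=5.0,
                               induction_delay_naive_min=0.0, doubling_time_min=1e7)
        pop = VirtualPopulation.seeded(cfg, 3)
        scope = VirtualMicroscope(pop, medium=RAFFINOSE)
        scope.set_medium(GALACTOSE)
        scope.wait(4.9 * 60)
        assert all(not c.transcribing for c in pop.cells)  # still raffinose
        scope.wait(10 * 60)
        assert all(c.transcribing for c in pop.cells)


class TestSimulateChase:
    def test_recovers_half_time_noise_free(self):
        trajs, t0 = simulate_chase(15.0, n_cells=40, noise_cv=0.0, seed=1)
        fit = cl.chase_half_time(trajs, t0)
        assert fit.half_time == pytest.approx(15.0, rel=1e-3)

    def test_trajectories_long_enough(self):
        trajs, _ = simulate_chase(15.0, n_cells=20, seed=2)
        assert max(t.n_points for t in trajs) >= 50

    def test_determinism(self):
        a = simulate_chase(12.0, n_cells=15, seed=5)[0]
        b = simulate_chase(12.0, n_cells=15, seed=5)[0]
        assert [t.fluorescence.tolist() for t in a] == [t.fluorescence.tolist() for t in b]
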