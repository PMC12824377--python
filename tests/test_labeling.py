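"""Training-label generation: P2 identification, chemical labels, edge
thresholds, and the edge-ring labeling."""

import numpy as np
import pytest

import thzchem as tz
from thzchem.extraction import extract_cube
from thzchem.labeling import (
    LabelingError,
    assign_pulse_labels,
    edge_threshold_for,
    edge_thresholds,
    find_background_arrival,
    label_cube,
    merge_datasets,
)
from thzchem.materials import BACKGROUND, EDGE
from thzchem.simulate import echo_indices, simulate_scene

from conftest import edge_adjacent_scene


class TestBackgroundArrival:
    def test_bare_metal_matches_analytic(self, bare_metal_cube, acq):
        grid = extract_cube(bare_metal_cube)
        arrival, tol = find_background_arrival(grid, bare_metal_cube.ground_truth)
        from thzchem.simulate import REF_T0_PS
        expected = (acq.t_metal_ps + REF_T0_PS) / acq.dt_ps
        assert abs(arrival - expected) <= 1.0

    def test_shift_equivariance(self, bare_metal_cube):
        import copy
        grid = extract_cube(bare_metal_cube)
        arrival, _ = find_background_arrival(grid, bare_metal_cube.ground_truth)
        shifted = copy.deepcopy(bare_metal_cube)
        shifted.field = np.roll(shifted.field, 40, axis=2)
        grid2 = extract_cube(shifted)
        arrival2, _ = find_background_arrival(grid2, shifted.ground_truth)
        assert arrival2 == arrival + 40

    def test_spread_within_tolerance(self, kno3_cube, kno3_grid):
        arrival, tol = find_background_arrival(kno3_grid, kno3_cube.ground_truth)
        for iy, ix in np.argwhere(kno3_cube.ground_truth == BACKGROUND):
            segs = kno3_grid[(iy, ix)].segments
            best = max(segs, key=lambda s: s.peak_amplitude)
            assert abs(best.peak_index - arrival) <= tol

    def test_no_background_rejected(self, kno3_grid, kno3_cube):
        gt = np.zeros_like(kno3_cube.ground_truth)  # all chemical
        with pytest.raises(LabelingError):
            find_background_arrival(kno3_grid, gt)


class TestAssignLabels:
    def test_interior_pulses_get_chemical_code(self, kno3_cube, kno3_grid):
        ds = label_cube(kno3_grid, kno3_cube.ground_truth, kno3_cube.material_map)
        gt = kno3_cube.ground_truth
        arrival, tol = find_background_arrival(kno3_grid, gt)
        for i in range(len(ds.y)):
            iy, ix = ds.pixels[i]
            if gt[iy, ix] == 4 and ds.roles[i] != "P2":
                assert ds.y[i] == 4

    def test_background_pixel_single_bg_segment(self, kno3_cube, kno3_grid):
        ds = label_cube(kno3_grid, kno3_cube.ground_truth, kno3_cube.material_map)
        gt = kno3_cube.ground_truth
        for i in range(len(ds.y)):
            iy, ix = ds.pixels[i]
            if gt[iy, ix] == BACKGROUND:
                assert ds.y[i] == BACKGROUND

    def test_edge_adjacent_four_pulses_p2_identified(self, acq_quiet,
                                                     cal_registry, calibrant):
        scene = edge_adjacent_scene()
        cube = simulate_scene(scene, acq_quiet, registry=cal_registry)
        grid = extract_cube(cube)
        arrival, tol = find_background_arrival(grid, cube.ground_truth)
        ds = assign_pulse_labels(grid, cube.ground_truth, cube.material_map,
                                 arrival, tol)
        segs = grid[(10, 6)].segments
        assert len(segs) == 4
        expected_p2 = echo_indices(calibrant, 3.0, acq_quiet)["P2"]
        labels = {}
        for i in range(len(ds.y)):
            if tuple(ds.pixels[i]) == (10, 6):
                labels[i] = (ds.roles[i], int(ds.y[i]))
        roles = [v for v in labels.values()]
        p2 = [v for v in roles if v[0] == "P2"]
        assert len(p2) == 1 and p2[0][1] == BACKGROUND
        chem = [v for v in roles if v[0] != "P2"]
        assert len(chem) == 3 and all(lab == 0 for _, lab in chem)

    def test_label_conservation(self, kno3_cube, kno3_grid):
        ds = label_cube(kno3_grid, kno3_cube.ground_truth, kno3_cube.material_map)
        n_segments = sum(len(ps.segments) for ps in kno3_grid.iter_sets())
        assert len(ds.y) == n_segments
        assert np.isin(ds.y, list(range(9))).all()

    def test_p2_recall_noise_free(self, acq_quiet, kno3_scene):
        cube = simulate_scene(kno3_scene, acq_quiet)
        grid = extract_cube(cube)
        arrival, tol = find_background_arrival(grid, cube.ground_truth)
        ds = assign_pulse_labels(grid, cube.ground_truth, cube.material_map,
                                 arrival, tol)
        # every segment at the metal-echo time is labeled background
        for i in range(len(ds.y)):
            if ds.roles[i] == "P2":
                assert ds.y[i] == BACKGROUND
        # and all background-timed segments were found: no non-P2 segment
        # sits within tolerance of the arrival
        for ps in grid.iter_sets():
            for seg in ps.segments:
                if abs(seg.peak_index - arrival) <= tol:
                    assert seg.label == BACKGROUND


class TestEdgeThreshold:
    def test_formula(self):
        amps = np.full(50, 1.0)
        amps[0] = 0.99  # avoid the degenerate all-equal fallback
        cfg = tz.LabelConfig(edge_factor=0.5)
        thr = edge_threshold_for(amps, 0.08, cfg)
        assert thr == pytest.approx(0.5, rel=0.01)

    def test_always_above_detection_threshold(self, kno3_cube, kno3_grid):
        arrival, tol = find_background_arrival(kno3_grid, kno3_cube.ground_truth)
        thr = edge_thresholds(kno3_grid, kno3_cube.ground_truth,
                              kno3_cube.material_map, arrival, tol)
        detection = kno3_grid.cfg.rel_threshold * kno3_grid.reference
        for t in thr.values():
            assert t > detection

    def test_degenerate_distribution_falls_back(self):
        with pytest.warns(UserWarning):
            thr = edge_threshold_for(np.full(10, 0.08), 0.08, tz.LabelConfig())
        assert thr == pytest.approx(0.08 * 1.25)

    def test_empty_sample_rejected(self):
        with pytest.raises(LabelingError):
            edge_threshold_for(np.array([]), 0.08)


class TestLabelEdges:
    def test_ring_flagged_and_consistent(self, kno3_cube, kno3_grid):
        ds = label_cube(kno3_grid, kno3_cube.ground_truth, kno3_cube.material_map)
        gt_edge = kno3_cube.ground_truth == EDGE
        # labeled edges never appear outside the ground-truth ring
        assert not (ds.edge_map & ~gt_edge).any()
        # every ring pixel with detectable sample pulses is flagged
        arrival, tol = find_background_arrival(kno3_grid, kno3_cube.ground_truth)
        for iy, ix in np.argwhere(gt_edge):
            has_sample_pulse = any(
                abs(s.peak_index - arrival) > tol
                for s in kno3_grid[(iy, ix)].segments)
            if has_sample_pulse:
                assert ds.edge_map[iy, ix]

    def test_interior_and_metal_not_edge(self, kno3_cube, kno3_grid):
        ds = label_cube(kno3_grid, kno3_cube.ground_truth, kno3_cube.material_map)
        interior = kno3_cube.ground_truth < BACKGROUND
        metal = kno3_cube.ground_truth == BACKGROUND
        assert not ds.edge_map[interior].any()
        assert not ds.edge_map[metal].any()


class TestMerge:
    def test_merge_counts(self, kno3_cube, kno3_grid):
        a = label_cube(kno3_grid, kno3_cube.ground_truth, kno3_cube.material_map,
                       scene_id=1)
        b = label_cube(kno3_grid, kno3_cube.ground_truth, kno3_cube.material_map,
                       scene_id=2)
        m = merge_datasets([a, b])
        assert len(m.y) == 2 * len(a.y)
        assert set(np.unique(m.scene_ids)) == {1, 2}
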