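"""Simulator physics: reference pulse, layered-stack echoes, scenes."""

import numpy as np
import pytest

import thzchem as tz
from thzchem.config import InvalidConfigError
from thzchem.materials import BACKGROUND, DEFAULT_MATERIALS, EDGE, MaterialSpec
from thzchem.simulate import (
    C_MM_PS,
    BenchmarkConfig,
    Placement,
    SceneSpec,
    SceneError,
    WaveformCube,
    disk_beam_overlap,
    echo_indices,
    ground_truth_maps,
    make_benchmark,
    make_disk_scene,
    make_reference_pulse,
    simulate_pixel,
    simulate_scene,
    stack_transfer_function,
)

from conftest import edge_adjacent_scene


class TestReferencePulse:
    def test_band_limited(self, acq):
        ref = make_reference_pulse(acq)
        spec = np.abs(np.fft.rfft(ref))
        freqs = np.fft.rfftfreq(acq.n_samples, acq.dt_ps)
        at_fmax = spec[np.argmin(np.abs(freqs - acq.f_max_thz))]
        assert at_fmax <= 0.01 * spec.max()

    def test_short_window_unit_peak(self):
        acq = tz.AcquisitionConfig(n_samples=650)
        ref = make_reference_pulse(acq)
        assert ref.max() == pytest.approx(1.0)
        # fully contained: ends decay to ~0
        assert np.abs(ref[0]) < 1e-8 and np.abs(ref[-1]) < 1e-8

    def test_time_reversal_same_amplitude_spectrum(self, acq):
        ref = make_reference_pulse(acq)
        a = np.abs(np.fft.rfft(ref))
        b = np.abs(np.fft.rfft(ref[::-1]))
        np.testing.assert_allclose(a, b, atol=1e-9 * a.max())

    def test_too_short_window_rejected(self):
        with pytest.raises(InvalidConfigError):
            make_reference_pulse(tz.AcquisitionConfig(n_samples=650), t0_ps=12.9)


class TestStackTransferFunction:
    def test_internal_echo_delay(self, acq):
        # inverse transform of the response shows the first internal echo
        # 2*n*d/c after the surface echo
        mat = MaterialSpec("X", 0, 1.5)
        n_fft = 2 * acq.n_samples
        freqs = np.fft.rfftfreq(n_fft, acq.dt_ps)
        H = stack_transfer_function(mat, 3.0, covered=False, freqs_thz=freqs)
        h = np.fft.irfft(H, n=n_fft)
        lag = 2 * 1.5 * 3.0 / C_MM_PS  # 30.02 ps
        surf = np.abs(h[:500]).argmax()
        window = np.abs(h[1000:2000])
        echo = 1000 + window.argmax()
        assert abs((echo - surf) * acq.dt_ps - lag) < 2 * acq.dt_ps

    def test_index_matched_surface_vanishes(self, acq):
        mat = MaterialSpec("vacuumlike", 0, 1.0)
        freqs = np.fft.rfftfreq(1024, acq.dt_ps)
        H = stack_transfer_function(mat, 2.0, covered=False, freqs_thz=freqs)
        # surface Fresnel term is zero; only the (delayed) metal echo remains,
        # whose modulus is 1 at every frequency
        np.testing.assert_allclose(np.abs(H), 1.0, atol=1e-9)

    def test_beer_lambert_doubling(self, acq):
        # doubling the baseline absorption squares the first internal echo's
        # amplitude ratio (exp(-2 alpha d) -> exp(-4 alpha d))
        freqs = np.fft.rfftfreq(4096, acq.dt_ps)
        m1 = MaterialSpec("a1", 0, 1.6, (), baseline_alpha=1.0)
        m2 = MaterialSpec("a2", 0, 1.6, (), baseline_alpha=2.0)
        m0 = MaterialSpec("a0", 0, 1.6, (), baseline_alpha=0.0)
        d = 3.0

        def p3_amp(m):
            H = stack_transfer_function(m, d, False, freqs, k_round_trips=1)
            h = np.fft.irfft(H, n=4096)
            return np.abs(h[300:]).max()

        # the Beer-Lambert factor dominates; the absorption-derived
        # extinction also perturbs the Fresnel coefficients at O(kappa^2)
        r1 = p3_amp(m1) / p3_amp(m0)
        r2 = p3_amp(m2) / p3_amp(m0)
        assert r2 == pytest.approx(r1**2, rel=1e-4)
        assert r1 == pytest.approx(np.exp(-2 * 1.0 * d / 10.0), rel=1e-4)

    def test_nonphysical_material_rejected(self):
        with pytest.raises(ValueError):
            MaterialSpec("bad", 0, -1.0)


class TestSimulatePixel:
    def test_bare_metal_single_flipped_echo(self, acq_quiet):
        scene = SceneSpec(placements=(), seed=0)
        tr = simulate_pixel(scene, (4, 4), acq_quiet)
        ref = make_reference_pulse(acq_quiet)
        t_idx = int(round((acq_quiet.t_metal_ps) / acq_quiet.dt_ps))
        # sign-flipped reference shifted to the metal-plane delay
        shifted = np.zeros_like(tr)
        shifted[t_idx:] = -ref[: tr.size - t_idx]
        np.testing.assert_allclose(tr, shifted, atol=1e-7)

    def test_edge_adjacent_four_echoes(self, acq_quiet, calibrant, cal_registry):
        scene = edge_adjacent_scene()
        tr = simulate_pixel(scene, (10, 6), acq_quiet, registry=cal_registry)
        peaks = tz.detect_peaks(tr, 1.0, tz.ExtractionConfig())
        assert len(peaks) >= 4
        expected = echo_indices(calibrant, 3.0, acq_quiet)
        found = [p for p, _ in peaks]
        for key in ("P1", "P2", "P3", "P4"):
            assert min(abs(f - expected[key]) for f in found) <= 1.0 + 1e-9

    def test_cover_adds_leading_echo(self, acq_quiet, cal_registry):
        base = edge_adjacent_scene()
        covered = SceneSpec(
            placements=base.placements, covered=True,
            surface_jitter_mm=0.0, thickness_jitter_mm=0.0, seed=base.seed)
        tr_u = simulate_pixel(base, (10, 6), acq_quiet, registry=cal_registry)
        tr_c = simulate_pixel(covered, (10, 6), acq_quiet, registry=cal_registry)
        pk_u = tz.detect_peaks(tr_u, 1.0, tz.ExtractionConfig())
        pk_c = tz.detect_peaks(tr_c, 1.0, tz.ExtractionConfig())
        first_u = pk_u[0][0]
        assert pk_c[0][0] < first_u  # extra echo precedes P1

    def test_outside_grid_rejected(self, acq):
        with pytest.raises(IndexError):
            simulate_pixel(SceneSpec(), (13, 0), acq)


class TestSimulateScene:
    def test_seeded_reproducibility(self, acq):
        scene = make_disk_scene("MCC", seed=11)
        a = simulate_scene(scene, acq)
        b = simulate_scene(scene, acq)
        assert np.array_equal(a.field, b.field)

    def test_empty_scene_all_background(self, acq, bare_metal_cube):
        assert (bare_metal_cube.ground_truth == BACKGROUND).all()

    def test_ground_truth_matches_rasterized_disk(self, acq):
        # chemical+edge pixel count equals a brute-force rasterized count of
        # pixels whose beam overlap exceeds the band floor
        scene = SceneSpec(placements=(Placement("MCC", (6.0, 6.0), 10.0, 3.0),))
        gt, _ = ground_truth_maps(scene, acq)
        lo = scene.edge_band[0]
        beam_r = acq.beam_diameter_mm / 2.0
        count = 0
        for iy in range(13):
            for ix in range(13):
                # numeric oracle: supersampled beam-footprint overlap
                xs = np.linspace(ix - beam_r, ix + beam_r, 101)
                ys = np.linspace(iy - beam_r, iy + beam_r, 101)
                gx, gy = np.meshgrid(xs, ys)
                in_beam = (gx - ix) ** 2 + (gy - iy) ** 2 <= beam_r**2
                in_disk = (gx - 6.0) ** 2 + (gy - 6.0) ** 2 <= 25.0
                frac = (in_beam & in_disk).sum() / in_beam.sum()
                if frac > lo:
                    count += 1
        assert ((gt == EDGE) | (gt < BACKGROUND)).sum() == count

    def test_overlapping_placements_rejected(self, acq):
        scene = SceneSpec(placements=(
            Placement("MCC", (5.0, 6.0), 10.0, 3.0),
            Placement("KNO3", (7.0, 6.0), 10.0, 3.0)))
        with pytest.raises(SceneError):
            simulate_scene(scene, acq)

    def test_overlap_fraction_analytic_vs_numeric(self, acq):
        rng = np.random.default_rng(5)
        for _ in range(20):
            dist = rng.uniform(0, 7)
            f = disk_beam_overlap(dist, 1.0, 5.0)
            th = np.linspace(0, 2 * np.pi, 400, endpoint=False)
            rr = np.linspace(0, 1, 200)
            R, T = np.meshgrid(rr, th)
            x = dist + R * np.cos(T)
            y = R * np.sin(T)
            inside = (x**2 + y**2 <= 25.0)
            numeric = (inside * R).sum() / R.sum()
            assert f == pytest.approx(numeric, abs=0.01)


class TestDelayAndAbsorptionInvariants:
    @pytest.mark.parametrize("name", ["MCC", "KNO3", "DCP", "TNT"])
    def test_delay_consistency_interior(self, name, acq_quiet):
        scene = make_disk_scene(name, seed=50)
        scene.surface_jitter_mm = 0.0
        scene.thickness_jitter_mm = 0.0
        d = scene.placements[0].thickness_mm
        mat = DEFAULT_MATERIALS[name]
        tr = simulate_pixel(scene, (6, 6), acq_quiet)
        peaks = tz.detect_peaks(tr, 1.0, tz.ExtractionConfig())
        lag = peaks[1][0] - peaks[0][0]
        expected = 2 * mat.n_refr * d / C_MM_PS / acq_quiet.dt_ps
        assert abs(lag - expected) <= 1.0 + 1e-9

    def test_p3_monotone_in_thickness_and_alpha(self, acq_quiet):
        def p3(d, alpha):
            mat = MaterialSpec("m", 0, 1.6, (), baseline_alpha=alpha)
            scene = SceneSpec(
                placements=(Placement("m", (6.0, 6.0), 10.0, d),),
                surface_jitter_mm=0.0, thickness_jitter_mm=0.0)
            tr = simulate_pixel(scene, (6, 6), acq_quiet,
                                registry={"m": mat})
            peaks = tz.detect_peaks(tr, 1.0, tz.ExtractionConfig())
            return peaks[1][1]

        assert p3(2.0, 0.5) > p3(3.0, 0.5) > p3(4.0, 0.5)
        assert p3(3.0, 0.2) > p3(3.0, 0.6) > p3(3.0, 1.2)


class TestCubeIO:
    def test_h5_roundtrip(self, kno3_cube, tmp_path):
        p = tmp_path / "cube.h5"
        kno3_cube.save_h5(p)
        back = WaveformCube.load_h5(p)
        assert np.array_equal(back.field, kno3_cube.field)
        assert np.array_equal(back.ground_truth, kno3_cube.ground_truth)
        assert back.acq.dt_ps == kno3_cube.acq.dt_ps

    def test_npz_roundtrip(self, kno3_cube, tmp_path):
        p = tmp_path / "cube.npz"
        kno3_cube.save_npz(p)
        back = WaveformCube.load_npz(p)
        assert np.array_equal(back.field, kno3_cube.field)
        assert np.array_equal(back.material_map, kno3_cube.material_map)


class TestBenchmarkPlan:
    def test_disjoint_seeds_and_counts(self):
        plan = make_benchmark(BenchmarkConfig(base_seed=3))
        seeds = plan.all_seeds()
        train = set(seeds["train"])
        assert len(plan.train) == 16
        assert len(plan.test_uncovered) == 8
        assert len(plan.test_covered) == 4
        for split in ("test_uncovered", "test_covered"):
            assert not train & set(seeds[split])
        # 8 distinct ground-truth chemical classes among training scenes
        gt_classes = {DEFAULT_MATERIALS[s.placements[0].material].class_index
                      for s in plan.train}
        assert gt_classes == set(range(8))

    def test_covered_in_train_rejected(self):
        with pytest.raises(SceneError):
            make_benchmark(BenchmarkConfig(train_covered=True))

    def test_covered_only_in_test(self):
        plan = make_benchmark(BenchmarkConfig())
        assert not any(s.covered for s in plan.train)
        assert all(s.covered for s in plan.test_covered)
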