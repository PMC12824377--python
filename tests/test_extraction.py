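"""Pulse detection/segmentation: unit examples, invariants, and the
brute-force oracle for the separation-constrained peak selection."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import find_peaks

import thzchem as tz
from thzchem.extraction import (
    detect_peaks,
    extract_cube,
    peak_amplitude_maps,
    reference_amplitude,
    segment_pulses,
)
from thzchem.materials import BACKGROUND


def brute_force_peaks(trace, reference, cfg):
    """Exhaustive oracle: best admissible subset of local maxima of |x|
    maximizing total amplitude; ties -> lexicographically smallest index
    tuple."""
    absx = np.abs(np.asarray(trace, float))
    idx, _ = find_peaks(absx, height=cfg.rel_threshold * reference)
    cand = list(zip(idx.tolist(), absx[idx].tolist()))
    best_total, best_set = 0.0, ()
    for r in range(len(cand) + 1):
        for subset in combinations(cand, r):
            ok = all(subset[j + 1][0] - subset[j][0] >= cfg.min_sep_samples
                     for j in range(len(subset) - 1))
            if not ok:
                continue
            total = sum(a for _, a in subset)
            key = tuple(p for p, _ in subset)
            if total > best_total + 1e-12 or (
                    abs(total - best_total) <= 1e-12 and key < best_set):
                best_total, best_set = total, key
    return [(p, absx[p]) for p in best_set]


def _impulse_trace(n, spikes):
    x = np.zeros(n)
    for p, a in spikes:
        x[p] = a
    return x


class TestDetectPeaks:
    def test_all_zero(self):
        assert detect_peaks(np.zeros(2000), 1.0, tz.ExtractionConfig()) == []

    def test_two_close_impulses_keep_larger(self):
        cfg = tz.ExtractionConfig()
        x = _impulse_trace(2000, [(500, 1.0), (800, 0.6)])
        assert detect_peaks(x, 1.0, cfg) == [(500, 1.0)]
        x = _impulse_trace(2000, [(500, 0.6), (800, 1.0)])
        assert detect_peaks(x, 1.0, cfg) == [(800, 1.0)]

    def test_tie_keeps_earlier(self):
        cfg = tz.ExtractionConfig()
        x = _impulse_trace(2000, [(500, 1.0), (800, 1.0)])
        assert detect_peaks(x, 1.0, cfg) == [(500, 1.0)]

    def test_total_amplitude_beats_greedy(self):
        # a greedy highest-first strategy would keep only the middle peak
        cfg = tz.ExtractionConfig(min_sep_samples=650)
        x = _impulse_trace(2000, [(100, 0.5), (400, 0.6), (750, 0.5)])
        got = detect_peaks(x, 1.0, cfg)
        assert [p for p, _ in got] == [100, 750]

    def test_negative_peaks_detected(self):
        cfg = tz.ExtractionConfig()
        x = _impulse_trace(2000, [(500, 1.0)])
        got = detect_peaks(-x, 1.0, cfg)
        assert got == [(500, 1.0)]

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cfg = tz.ExtractionConfig(min_sep_samples=int(rng.integers(50, 700)))
        n = int(rng.integers(400, 2000))
        n_spikes = int(rng.integers(0, 8))
        pos = rng.choice(np.arange(5, n - 5), size=n_spikes, replace=False)
        x = np.zeros(n)
        for p in pos:
            x[p] = rng.uniform(-1.0, 1.0)
        x += 0.01 * rng.standard_normal(n)
        got = detect_peaks(x, 1.0, cfg)
        want = brute_force_peaks(x, 1.0, cfg)
        assert [p for p, _ in got] == [p for p, _ in want]

    def test_shift_equivariance(self):
        cfg = tz.ExtractionConfig()
        rng = np.random.default_rng(0)
        x = np.zeros(3000)
        for p in (400, 1300, 2400):
            x[p] = rng.uniform(0.5, 1.0)
        base = [p for p, _ in detect_peaks(x, 1.0, cfg)]
        k = 37
        shifted = np.roll(x, k)
        got = [p for p, _ in detect_peaks(shifted, 1.0, cfg)]
        assert got == [p + k for p in base]

    def test_amplitude_scale_invariance(self):
        cfg = tz.ExtractionConfig()
        x = _impulse_trace(3000, [(400, 0.3), (1300, 0.9)])
        a = [p for p, _ in detect_peaks(x, 1.0, cfg)]
        b = [p for p, _ in detect_peaks(7.0 * x, 7.0, cfg)]
        assert a == b


class TestSegmentPulses:
    def test_centering(self):
        cfg = tz.ExtractionConfig()
        trace = np.arange(10100, dtype=float)
        segs = segment_pulses(trace, [(325, 1.0)], cfg)
        assert segs[0].start_index == 0
        np.testing.assert_array_equal(segs[0].samples, trace[0:650])

    def test_boundary_zero_pad(self):
        cfg = tz.ExtractionConfig()
        trace = np.ones(10100)
        segs = segment_pulses(trace, [(100, 1.0)], cfg)
        assert (segs[0].samples[:225] == 0).all()
        assert (segs[0].samples[225:] == 1).all()

    def test_segment_length_always_650(self, kno3_grid):
        for seg in kno3_grid.iter_segments():
            assert seg.samples.size == 650

    def test_overflow_keeps_largest_in_arrival_order(self):
        cfg = tz.ExtractionConfig(max_pulses_per_pixel=2, min_sep_samples=10)
        peaks = [(100, 0.3), (200, 0.9), (300, 0.5), (400, 0.2)]
        segs = segment_pulses(np.zeros(1000), peaks, cfg)
        assert [(s.peak_index, s.rank) for s in segs] == [(200, 1), (300, 2)]

    def test_no_overlapping_segments_at_defaults(self, kno3_grid):
        w = kno3_grid.cfg.window_samples
        for ps in kno3_grid.iter_sets():
            idx = sorted(s.peak_index for s in ps.segments)
            for a, b in zip(idx, idx[1:]):
                assert b - a >= kno3_grid.cfg.min_sep_samples


class TestReferenceAmplitude:
    def test_border_metal_echo_unit(self, kno3_cube):
        ref = reference_amplitude(kno3_cube)
        ny, nx, _ = kno3_cube.field.shape
        border = [(iy, ix) for iy in range(ny) for ix in range(nx)
                  if iy in (0, ny - 1) or ix in (0, nx - 1)]
        oracle = max(np.abs(kno3_cube.field[iy, ix]).max() for iy, ix in border)
        assert ref == oracle
        assert ref == pytest.approx(1.0, abs=0.01)

    def test_homogeneity(self, kno3_cube):
        import copy
        doubled = copy.deepcopy(kno3_cube)
        doubled.field = 2.0 * doubled.field
        assert reference_amplitude(doubled) == pytest.approx(
            2.0 * reference_amplitude(kno3_cube))

    def test_all_zero_cube_rejected(self, acq):
        cube = tz.WaveformCube(np.zeros((3, 3, 10100)), acq)
        with pytest.raises(ValueError):
            reference_amplitude(cube)


class TestExtractCube:
    def test_bare_metal_single_segment_everywhere(self, bare_metal_cube):
        grid = extract_cube(bare_metal_cube)
        for ps in grid.iter_sets():
            assert len(ps.segments) == 1

    def test_interior_has_surface_and_bottom_echo(self, kno3_cube):
        grid = extract_cube(kno3_cube)
        gt = kno3_cube.ground_truth
        for iy, ix in np.argwhere(gt < BACKGROUND):
            assert len(grid[(iy, ix)].segments) >= 2

    def test_determinism(self, kno3_cube):
        a = extract_cube(kno3_cube)
        b = extract_cube(kno3_cube)
        for sa, sb in zip(a.iter_segments(), b.iter_segments()):
            assert sa.peak_index == sb.peak_index
            np.testing.assert_array_equal(sa.samples, sb.samples)


class TestPeakAmplitudeMaps:
    def test_rank_beyond_counts_is_zero(self, kno3_grid):
        assert (peak_amplitude_maps(kno3_grid, 8) == 0).all()

    def test_rank1_bare_metal_constant(self, bare_metal_cube):
        grid = extract_cube(bare_metal_cube)
        m = peak_amplitude_maps(grid, 1)
        assert m.std() < 1e-3 * m.mean()

    def test_rank1_traces_disk_geometry(self, kno3_cube, kno3_grid):
        m = peak_amplitude_maps(kno3_grid, 1)
        interior = kno3_cube.ground_truth < BACKGROUND
        assert (m[interior] > 0).all()

    def test_pulse_store_roundtrip(self, kno3_grid, tmp_path):
        kno3_grid.save_h5(tmp_path / "pulses.h5")
        df = kno3_grid.to_dataframe()
        assert set(df.columns) >= {"iy", "ix", "rank", "peak_index", "peak_amp"}
        assert len(df) == sum(len(ps.segments) for ps in kno3_grid.iter_sets())
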