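"""Pulse detection, segmentation, and peak-amplitude maps.

Detection runs on the absolute value of the trace (metal echoes are
sign-flipped relative to the incident field), keeping every local maximum
that reaches the relative threshold against a background reference
reflection.  Among threshold-passing candidates, the admissible subset
(pairwise index separation >= ``min_sep_samples``) maximizing the total
peak amplitude is selected exactly by dynamic programming; ties resolve to
the lexicographically earliest index set.  Each selected peak is cut into
a 650-sample (13-ps) segment centered on the peak, zero-padded at trace
boundaries, and each pixel keeps at most 8 segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .config import ExtractionConfig
from .simulate import WaveformCube


@dataclass
class PulseSegment:
    """One windowed pulse cut from a pixel's trace."""

    pixel: Tuple[int, int]
    start_index: int
    samples: np.ndarray  # [window_samples], signed waveform
    peak_index: int  # global index in the parent trace
    peak_amplitude: float
    rank: int  # order of arrival, 1-based
    role: Optional[str] = None  # P1/P2/P3/P4plus/cover/unknown
    label: Optional[int] = None  # training-time class code


@dataclass
class PixelPulseSet:
    """All segments of one pixel, zero-padded to a fixed 8 x 650 stack."""

    pixel: Tuple[int, int]
    segments: List[PulseSegment] = field(default_factory=list)

    @property
    def pad_count(self) -> int:
        return max(0, 8 - len(self.segments))

    def stack(self, set_size: int = 8, window: int = 650) -> np.ndarray:
        out = np.zeros((set_size, window))
        for i, seg in enumerate(self.segments[:set_size]):
            out[i] = seg.samples
        return out


class PulseGrid:
    """Grid of PixelPulseSets for a whole cube."""

    def __init__(self, sets: List[List[PixelPulseSet]], reference: float,
                 cfg: ExtractionConfig):
        self.sets = sets
        self.reference = reference
        self.cfg = cfg

    @property
    def grid_shape(self) -> Tuple[int, int]:
        return len(self.sets), len(self.sets[0])

    def __getitem__(self, pixel: Tuple[int, int]) -> PixelPulseSet:
        return self.sets[pixel[0]][pixel[1]]

    def iter_sets(self):
        for row in self.sets:
            yield from row

    def iter_segments(self):
        for ps in self.iter_sets():
            yield from ps.segments

    def stacks(self) -> np.ndarray:
        """[ny, nx, 8, window] zero-padded pulse stacks."""
        ny, nx = self.grid_shape
        w = self.cfg.window_samples
        out = np.zeros((ny, nx, 8, w))
        for iy in range(ny):
            for ix in range(nx):
                out[iy, ix] = self.sets[iy][ix].stack(8, w)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "iy": seg.pixel[0], "ix": seg.pixel[1], "rank": seg.rank,
                "peak_index": seg.peak_index, "peak_amp": seg.peak_amplitude,
                "label": -1 if seg.label is None else seg.label,
                "role": seg.role or "",
            }
            for seg in self.iter_segments()
        ]
        return pd.DataFrame(rows, columns=["iy", "ix", "rank", "peak_index",
                                           "peak_amp", "label", "role"])

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def save_h5(self, path) -> None:
        ny, nx = self.grid_shape
        w = self.cfg.window_samples
        pulses = self.stacks()
        peak_index = np.full((ny, nx, 8), -1, dtype=np.int64)
        peak_amp = np.zeros((ny, nx, 8))
        pad = np.zeros((ny, nx), dtype=np.int64)
        for iy in range(ny):
            for ix in range(nx):
                ps = self.sets[iy][ix]
                pad[iy, ix] = ps.pad_count
                for i, seg in enumerate(ps.segments[:8]):
                    peak_index[iy, ix, i] = seg.peak_index
                    peak_amp[iy, ix, i] = seg.peak_amplitude
        with h5py.File(path, "w") as fh:
            fh.create_dataset("pulses", data=pulses)
            fh.create_dataset("peak_index", data=peak_index)
            fh.create_dataset("peak_amp", data=peak_amp)
            fh.create_dataset("pad_count", data=pad)
            fh.attrs["reference"] = self.reference
            fh.attrs["window_samples"] = w


# ---------------------------------------------------------------------------
# operations


def reference_amplitude(cube: WaveformCube,
                        background_pixels: Optional[Sequence[Tuple[int, int]]] = None
                        ) -> float:
    """Peak |field| of the background reference reflection.

    Default background region: the border pixels of the raster grid (a
    sample disk never reaches the field-of-view border in the supported
    geometries)."""
    ny, nx, _ = cube.field.shape
    if background_pixels is None:
        background_pixels = [(iy, ix) for iy in range(ny) for ix in range(nx)
                             if iy in (0, ny - 1) or ix in (0, nx - 1)]
    if len(background_pixels) == 0:
        raise ValueError("need at least one background pixel")
    ref = max(float(np.max(np.abs(cube.field[iy, ix]))) for iy, ix in background_pixels)
    if ref <= 0:
        raise ValueError("all-zero background region: cannot derive a reference")
    return ref


def detect_peaks(trace: np.ndarray, reference: float,
                 cfg: ExtractionConfig) -> List[Tuple[int, float]]:
    """Detect pulse peaks in one trace.

    Candidates are local maxima of |trace| with amplitude >=
    ``rel_threshold * reference``; the returned subset satisfies pairwise
    separation >= ``min_sep_samples`` and maximizes total amplitude
    (exact DP; ties -> lexicographically earliest index set).  Sorted by
    index."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    absx = np.abs(np.asarray(trace, dtype=float))
    height = cfg.rel_threshold * reference
    idx, _ = find_peaks(absx, height=height)
    if idx.size == 0:
        return []
    amps = absx[idx]
    order = np.argsort(idx)
    idx, amps = idx[order], amps[order]
    n = idx.size
    sep = cfg.min_sep_samples
    # suffix DP: best[i] = best achievable total using candidate i first
    best = np.zeros(n)
    nxt = np.full(n, -1, dtype=int)
    for i in range(n - 1, -1, -1):
        best_tail = 0.0
        best_j = -1
        for j in range(i + 1, n):
            if idx[j] - idx[i] >= sep and best[j] > best_tail + 1e-15:
                best_tail = best[j]
                best_j = j
        best[i] = amps[i] + best_tail
        nxt[i] = best_j
    total = best.max()
    # reconstruct lexicographically earliest optimal chain
    out: List[Tuple[int, float]] = []
    remaining = total
    pos = -1  # index constraint start
    i = 0
    while True:
        chosen = -1
        for j in range(i, n):
            if pos >= 0 and idx[j] - idx[pos] < sep:
                continue
            if abs(best[j] - remaining) <= 1e-12 * max(1.0, total):
                chosen = j
                break
        if chosen < 0:
            break
        out.append((int(idx[chosen]), float(amps[chosen])))
        remaining = remaining - amps[chosen]
        pos = chosen
        i = chosen + 1
        if remaining <= 1e-12 * max(1.0, total):
            break
    return out


def segment_pulses(trace: np.ndarray, peaks: Sequence[Tuple[int, float]],
                   cfg: ExtractionConfig,
                   pixel: Tuple[int, int] = (0, 0)) -> List[PulseSegment]:
    """Cut one window per peak, centered on the peak index.

    The window is [p - w//2, p + w - w//2); portions outside the trace are
    zero-padded.  At most ``max_pulses_per_pixel`` segments are kept (the
    largest amplitudes win), re-ranked by arrival order."""
    trace = np.asarray(trace, dtype=float)
    w = cfg.window_samples
    half = w // 2
    kept = list(peaks)
    if len(kept) > cfg.max_pulses_per_pixel:
        kept = sorted(kept, key=lambda pa: (-pa[1], pa[0]))[: cfg.max_pulses_per_pixel]
        kept.sort(key=lambda pa: pa[0])
    segments = []
    for rank, (p, amp) in enumerate(kept, start=1):
        start = p - half
        window = np.zeros(w)
        lo = max(0, start)
        hi = min(trace.size, start + w)
        window[lo - start: hi - start] = trace[lo:hi]
        segments.append(PulseSegment(pixel=pixel, start_index=start, samples=window,
                                     peak_index=int(p), peak_amplitude=float(amp),
                                     rank=rank))
    return segments


def extract_cube(cube: WaveformCube, cfg: ExtractionConfig | None = None,
                 background_pixels=None) -> PulseGrid:
    """Run reference estimation once, then detect and segment every pixel."""
    cfg = cfg or ExtractionConfig()
    cfg.validate()
    ref = reference_amplitude(cube, background_pixels)
    ny, nx, _ = cube.field.shape
    sets: List[List[PixelPulseSet]] = []
    for iy in range(ny):
        row = []
        for ix in range(nx):
            trace = cube.field[iy, ix]
            peaks = detect_peaks(trace, ref, cfg)
            segs = segment_pulses(trace, peaks, cfg, pixel=(iy, ix))
            row.append(PixelPulseSet(pixel=(iy, ix), segments=segs))
        sets.append(row)
    return PulseGrid(sets, ref, cfg)


def peak_amplitude_maps(grid: PulseGrid, rank: int) -> np.ndarray:
    """Map of the rank-th arrival's peak amplitude per pixel (0 where the
    pixel has fewer pulses)."""
    if rank < 1:
        raise ValueError("rank must be >= 1")
    ny, nx = grid.grid_shape
    out = np.zeros((ny, nx))
    for ps in grid.iter_sets():
        if len(ps.segments) >= rank:
            iy, ix = ps.pixel
            out[iy, ix] = ps.segments[rank - 1].peak_amplitude
    return out
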