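"""Training-label generation from extracted pulses and scene ground truth.

The holder-plane echo (P2) is identified by its consistent arrival time
across the scanned area and labeled background wherever it occurs.  Every
other detected pulse at a chemical pixel inherits that pixel's chemical
code.  A material-specific amplitude threshold -- above the global
detection threshold but below the bulk amplitude level -- separates
edge pixels (weak, scattering-dominated pulses) from bulk sample pixels.
In covered scenes the leading cover reflections are recognized by their
early arrival and excluded from training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import LabelConfig
from .extraction import PulseGrid
from .materials import BACKGROUND, EDGE, CLASS_NAMES


class LabelingError(ValueError):
    pass


@dataclass
class LabeledPulseDataset:
    """Flat per-segment training table plus pixel-level edge codes.

    ``X`` holds the signed 650-sample windows; ``y`` the class codes
    (0..7 chemicals, 8 background).  ``from_edge`` flags segments cut at
    edge-labeled pixels; ``excluded`` flags segments (cover reflections)
    that must not enter training.
    """

    X: np.ndarray  # [n, window]
    y: np.ndarray  # [n] class codes
    pixels: np.ndarray  # [n, 2]
    roles: List[str]
    from_edge: np.ndarray  # [n] bool
    excluded: np.ndarray  # [n] bool
    scene_ids: np.ndarray  # [n]
    edge_map: Optional[np.ndarray] = None  # [ny, nx] bool, pixel-level

    def training_mask(self, include_edge_pixels: bool = False) -> np.ndarray:
        mask = ~self.excluded
        if not include_edge_pixels:
            mask &= ~self.from_edge
        return mask

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iy": self.pixels[:, 0], "ix": self.pixels[:, 1],
            "label": self.y, "role": self.roles,
            "from_edge": self.from_edge, "excluded": self.excluded,
            "scene_id": self.scene_ids,
        })


def find_background_arrival(grid: PulseGrid, ground_truth: np.ndarray
                            ) -> Tuple[int, int]:
    """Modal arrival index of the dominant pulse over background pixels,
    with a spread-derived tolerance (in samples).  The dominant (largest
    amplitude) pulse at a background pixel is the holder-plane reflection,
    which stays robust even when a cover layer adds an earlier weak echo."""
    bg = np.argwhere(ground_truth == BACKGROUND)
    if bg.size == 0:
        raise LabelingError("ground truth contains no background pixels")
    arrivals = []
    for iy, ix in bg:
        segs = grid[(iy, ix)].segments
        if segs:
            arrivals.append(max(segs, key=lambda s: s.peak_amplitude).peak_index)
    if not arrivals:
        raise LabelingError("no pulses detected on any background pixel")
    arrivals = np.asarray(arrivals)
    vals, counts = np.unique(arrivals, return_counts=True)
    mode = int(vals[np.argmax(counts)])
    spread = int(np.max(np.abs(arrivals - mode)))
    tol = max(3, spread + 1)
    return mode, tol


def assign_pulse_labels(grid: PulseGrid, ground_truth: np.ndarray,
                        material_map: np.ndarray,
                        arrival: int, tolerance: int,
                        covered: bool = False,
                        scene_id: int = 0,
                        manual_overrides: Optional[pd.DataFrame] = None
                        ) -> LabeledPulseDataset:
    """Label every extracted segment.

    Segments arriving within ``tolerance`` of the background arrival are
    P2 -> background regardless of pixel.  Other segments inherit the
    pixel's chemical code (ground truth for chemical pixels, underlying
    material for edge pixels, background otherwise).  In covered scenes,
    segments arriving well before the earliest possible sample-surface
    echo are flagged as cover reflections and excluded from training.
    ``manual_overrides`` (columns iy, ix, rank, label) supports real-data
    relabeling where no simulator ground truth exists.
    """
    overrides: Dict[Tuple[int, int, int], int] = {}
    if manual_overrides is not None:
        for _, row in manual_overrides.iterrows():
            overrides[(int(row.iy), int(row.ix), int(row["rank"]))] = int(row.label)
    # earliest credible sample-surface echo: 5-mm cavity depth of air path
    cover_cutoff = arrival - int(round(2 * 5.0 / 0.299792458 / 0.02))
    X, y, px, roles, from_edge, excluded = [], [], [], [], [], []
    for ps in grid.iter_sets():
        iy, ix = ps.pixel
        gt = int(ground_truth[iy, ix])
        if gt not in CLASS_NAMES:
            raise LabelingError(f"pixel ({iy},{ix}) has unknown ground truth {gt}")
        for seg in ps.segments:
            is_p2 = abs(seg.peak_index - arrival) <= tolerance
            is_cover = covered and seg.peak_index < cover_cutoff
            if (iy, ix, seg.rank) in overrides:
                label = overrides[(iy, ix, seg.rank)]
                role = "manual"
            elif is_p2:
                label, role = BACKGROUND, "P2"
            elif is_cover:
                label, role = BACKGROUND, "cover"
            elif gt == BACKGROUND:
                label, role = BACKGROUND, "unknown"
            elif gt == EDGE:
                mat = int(material_map[iy, ix])
                if mat < 0:
                    raise LabelingError(f"edge pixel ({iy},{ix}) lacks a material")
                label, role = mat, "unknown"
            else:
                label, role = gt, "unknown"
            seg.label = label
            seg.role = role
            X.append(seg.samples)
            y.append(label)
            px.append((iy, ix))
            roles.append(role)
            from_edge.append(gt == EDGE)
            excluded.append(is_cover)
    n = len(X)
    return LabeledPulseDataset(
        X=np.asarray(X) if n else np.zeros((0, grid.cfg.window_samples)),
        y=np.asarray(y, dtype=np.int64),
        pixels=np.asarray(px, dtype=np.int64).reshape(n, 2),
        roles=roles,
        from_edge=np.asarray(from_edge, dtype=bool),
        excluded=np.asarray(excluded, dtype=bool),
        scene_ids=np.full(n, scene_id, dtype=np.int64),
    )


def edge_threshold_for(material_pixel_amplitudes: np.ndarray,
                       detection_threshold: float,
                       cfg: LabelConfig | None = None) -> float:
    """Material-specific edge/bulk amplitude threshold.

    threshold = max(detection*(1+margin), edge_factor * bulk quantile),
    required to stay strictly between the detection threshold and the bulk
    level; degenerate distributions fall back to detection*(1+margin)."""
    cfg = cfg or LabelConfig()
    cfg.validate()
    amps = np.asarray(material_pixel_amplitudes, dtype=float)
    if amps.size == 0:
        raise LabelingError("empty amplitude sample")
    floor = detection_threshold * (1.0 + cfg.threshold_margin)
    bulk = float(np.quantile(amps, cfg.edge_quantile))
    thr = max(floor, cfg.edge_factor * bulk)
    if thr >= bulk:
        warnings.warn("degenerate amplitude distribution: edge threshold "
                      "falls back to just above the detection threshold")
        return floor
    return thr


def material_bulk_amplitudes(grid: PulseGrid, ground_truth: np.ndarray,
                             material_map: np.ndarray,
                             arrival: int, tolerance: int) -> Dict[int, np.ndarray]:
    """Per-material distribution of the strongest non-P2 pulse amplitude
    over bulk (chemical-labeled) pixels."""
    out: Dict[int, List[float]] = {}
    for ps in grid.iter_sets():
        iy, ix = ps.pixel
        gt = int(ground_truth[iy, ix])
        if gt >= BACKGROUND:
            continue
        amps = [seg.peak_amplitude for seg in ps.segments
                if abs(seg.peak_index - arrival) > tolerance]
        if amps:
            out.setdefault(gt, []).append(max(amps))
    return {k: np.asarray(v) for k, v in out.items()}


def edge_thresholds(grid: PulseGrid, ground_truth: np.ndarray,
                    material_map: np.ndarray, arrival: int, tolerance: int,
                    cfg: LabelConfig | None = None) -> Dict[int, float]:
    """Edge threshold per material present in the scene (absolute units)."""
    cfg = cfg or LabelConfig()
    detection = grid.cfg.rel_threshold * grid.reference
    bulk = material_bulk_amplitudes(grid, ground_truth, material_map,
                                    arrival, tolerance)
    return {mat: edge_threshold_for(amps, detection, cfg)
            for mat, amps in bulk.items()}


def label_edges(grid: PulseGrid, thresholds: Dict[int, float],
                material_map: np.ndarray, arrival: int, tolerance: int,
                covered: bool = False) -> np.ndarray:
    """Binary edge grid: a pixel is an edge iff it has at least one
    detected non-P2 (non-cover) pulse and all such pulses fall below its
    material's threshold.  Pixels without sample pulses are not edges."""
    ny, nx = grid.grid_shape
    out = np.zeros((ny, nx), dtype=bool)
    cover_cutoff = arrival - int(round(2 * 5.0 / 0.299792458 / 0.02))
    for ps in grid.iter_sets():
        iy, ix = ps.pixel
        amps = [seg.peak_amplitude for seg in ps.segments
                if abs(seg.peak_index - arrival) > tolerance
                and not (covered and seg.peak_index < cover_cutoff)]
        if not amps:
            continue
        mat = int(material_map[iy, ix])
        thr = thresholds.get(mat)
        if thr is None:
            # sample pulses at a pixel with no known material: use the most
            # permissive threshold available
            if not thresholds:
                continue
            thr = max(thresholds.values())
        out[iy, ix] = max(amps) < thr
    return out


def label_cube(grid: PulseGrid, ground_truth: np.ndarray, material_map: np.ndarray,
               cfg: LabelConfig | None = None, covered: bool = False,
               scene_id: int = 0) -> LabeledPulseDataset:
    """Full labeling pass for one cube: P2 arrival, per-segment labels,
    material thresholds, and the pixel-level edge map."""
    cfg = cfg or LabelConfig()
    arrival, tol = find_background_arrival(grid, ground_truth)
    if cfg.arrival_tolerance_samples is not None:
        tol = cfg.arrival_tolerance_samples
    ds = assign_pulse_labels(grid, ground_truth, material_map, arrival, tol,
                             covered=covered, scene_id=scene_id)
    thresholds = edge_thresholds(grid, ground_truth, material_map, arrival, tol, cfg)
    ds.edge_map = label_edges(grid, thresholds, material_map, arrival, tol,
                              covered=covered)
    return ds


def merge_datasets(datasets: List[LabeledPulseDataset]) -> LabeledPulseDataset:
    """Concatenate per-scene labeled datasets (edge maps are dropped)."""
    if not datasets:
        raise LabelingError("no datasets to merge")
    return LabeledPulseDataset(
        X=np.concatenate([d.X for d in datasets]),
        y=np.concatenate([d.y for d in datasets]),
        pixels=np.concatenate([d.pixels for d in datasets]),
        roles=sum((d.roles for d in datasets), []),
        from_edge=np.concatenate([d.from_edge for d in datasets]),
        excluded=np.concatenate([d.excluded for d in datasets]),
        scene_ids=np.concatenate([d.scene_ids for d in datasets]),
    )
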