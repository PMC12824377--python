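"""Decision fusion and spatial post-processing of per-pixel predictions.

Per-pulse ClassNet probabilities are aggregated per pixel by
winner-takes-all (global argmax over every pulse/class pair; a mean-
probability alternative is available behind ``FusionConfig.aggregation``).
A pixel flagged by EdgeNet whose winning class probability stays below the
confidence threshold (0.95) becomes Edge; all other pixels keep their
aggregated class.  The map is then cleaned with a single synchronous 3x3
majority vote (center included, truncated border neighborhoods, ties keep
the original label) and small 8-connected components are dissolved into
their surroundings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import ExtractionConfig, FusionConfig
from .extraction import PulseGrid, extract_cube
from .materials import BACKGROUND, EDGE, CLASS_NAMES
from .simulate import WaveformCube

N_CODES = 10  # 0..7 chemicals, 8 background, 9 edge


@dataclass
class ClassMap:
    """Categorical image over {chemicals, background, edge} plus the
    winning class probability per pixel."""

    labels: np.ndarray  # [ny, nx] int codes
    maxprob: np.ndarray  # [ny, nx] in [0, 1]

    def save_csv(self, path) -> None:
        pd.DataFrame(self.labels).to_csv(path, index=False, header=False)

    def save_png(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib import colors

        cmap = plt.get_cmap("tab10", N_CODES)
        fig, ax = plt.subplots(figsize=(5, 5))
        im = ax.imshow(self.labels, cmap=cmap, norm=colors.NoNorm(), origin="lower")
        cbar = fig.colorbar(im, ax=ax, ticks=range(N_CODES))
        cbar.ax.set_yticklabels([CLASS_NAMES[i] for i in range(N_CODES)])
        ax.set_xlabel("x (pixels)")
        ax.set_ylabel("y (pixels)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def aggregate_pixel(prob_vectors: Sequence[np.ndarray],
                    no_pulses: bool = False,
                    aggregation: str = "max") -> Tuple[int, float]:
    """Combine the per-pulse class probabilities of one pixel.

    ``max``: global argmax over all (pulse, class) pairs; ``mean``:
    argmax of the pulse-averaged probability vector.  Pixels with no
    pulses are background with probability 1 (``no_pulses`` must be set).
    Ties resolve to the lower class code."""
    if len(prob_vectors) == 0:
        if not no_pulses:
            raise ValueError("empty probability list without no_pulses flag")
        return BACKGROUND, 1.0
    mat = np.asarray(prob_vectors)  # [n_pulses, n_classes]
    if aggregation == "mean":
        vec = mat.mean(axis=0)
        cls = int(np.argmax(vec))
        return cls, float(vec[cls])
    best = mat.max(axis=0)  # per-class best over pulses
    cls = int(np.argmax(best))  # argmax takes the lowest index on ties
    return cls, float(best[cls])


def fuse(edge_prob: np.ndarray, pixel_class: int, pixel_maxprob: float,
         cfg: FusionConfig | None = None) -> int:
    """Edge iff EdgeNet votes edge and the class confidence is below the
    threshold; otherwise the pixel keeps its aggregated class."""
    cfg = cfg or FusionConfig()
    if edge_prob[0] > 0.5 and pixel_maxprob < cfg.prob_threshold:
        return EDGE
    return pixel_class


def majority_vote(cmap: ClassMap, cfg: FusionConfig | None = None) -> ClassMap:
    """One synchronous pass of 3x3 modal filtering (center included;
    borders use the truncated neighborhood; ties keep the original)."""
    cfg = cfg or FusionConfig()
    labels = cmap.labels
    ny, nx = labels.shape
    r = cfg.vote_window // 2
    counts = np.zeros((N_CODES, ny, nx), dtype=np.int32)
    onehot = np.zeros((N_CODES, ny, nx), dtype=np.int32)
    for c in range(N_CODES):
        onehot[c] = labels == c
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            ys = slice(max(0, dy), min(ny, ny + dy))
            yd = slice(max(0, -dy), min(ny, ny - dy))
            xs = slice(max(0, dx), min(nx, nx + dx))
            xd = slice(max(0, -dx), min(nx, nx - dx))
            counts[:, yd, xd] += onehot[:, ys, xs]
    top = counts.max(axis=0)
    winner = counts.argmax(axis=0)  # lowest code on ties
    n_winners = (counts == top[None]).sum(axis=0)
    out = np.where(n_winners > 1, labels, winner)
    return ClassMap(out.astype(labels.dtype), cmap.maxprob.copy())


def morph_clean(cmap: ClassMap, cfg: FusionConfig | None = None) -> ClassMap:
    """Dissolve small connected components of non-background labels into
    the modal label of their boundary pixels (8-connectivity)."""
    cfg = cfg or FusionConfig()
    structure = (np.ones((3, 3), dtype=int) if cfg.connectivity == 8
                 else ndimage.generate_binary_structure(2, 1))
    labels = cmap.labels.copy()
    for code in sorted(set(np.unique(labels)) - {BACKGROUND}):
        comp, n = ndimage.label(cmap.labels == code, structure=structure)
        for ci in range(1, n + 1):
            mask = comp == ci
            if mask.sum() >= cfg.min_component:
                continue
            ring = ndimage.binary_dilation(mask, structure=structure) & ~mask
            if not ring.any():
                continue
            vals, counts = np.unique(cmap.labels[ring], return_counts=True)
            labels[mask] = int(vals[np.argmax(counts)])  # lowest code on ties
    return ClassMap(labels, cmap.maxprob.copy())


def infer_cube(cube: WaveformCube, classnet, edgenet,
               extraction_cfg: ExtractionConfig | None = None,
               fusion_cfg: FusionConfig | None = None,
               grid: Optional[PulseGrid] = None) -> ClassMap:
    """End-to-end inference: extract pulses, run both networks, fuse and
    post-process into the final class map."""
    fusion_cfg = fusion_cfg or FusionConfig()
    fusion_cfg.validate()
    if grid is None:
        grid = extract_cube(cube, extraction_cfg)
    ny, nx = grid.grid_shape
    # batch every segment through ClassNet
    segs = list(grid.iter_segments())
    seg_probs = (classnet.predict_proba(np.stack([s.samples for s in segs]))
                 if segs else np.zeros((0, 9)))
    probs_by_pixel = {}
    for s, p in zip(segs, seg_probs):
        probs_by_pixel.setdefault(s.pixel, []).append(p)
    # batch every pixel stack through EdgeNet
    stacks = grid.stacks().reshape(ny * nx, 8, -1)
    edge_probs = edgenet.predict_proba(stacks).reshape(ny, nx, 2)
    labels = np.zeros((ny, nx), dtype=np.int64)
    maxprob = np.zeros((ny, nx))
    for iy in range(ny):
        for ix in range(nx):
            vecs = probs_by_pixel.get((iy, ix), [])
            cls, p = aggregate_pixel(vecs, no_pulses=not vecs,
                                     aggregation=fusion_cfg.aggregation)
            labels[iy, ix] = fuse(edge_probs[iy, ix], cls, p, fusion_cfg)
            maxprob[iy, ix] = p
    cmap = ClassMap(labels, maxprob)
    cmap = majority_vote(cmap, fusion_cfg)
    cmap = morph_clean(cmap, fusion_cfg)
    return cmap
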