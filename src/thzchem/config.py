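"""Configuration objects for the terahertz chemical-imaging pipeline.

Every tunable of the pipeline lives in one of the dataclasses below so a
whole run can be serialized to YAML, hashed, and reproduced.  Defaults
mirror the acquisition geometry of a reflection-mode THz-TDS raster
scanner: 10,100 time samples at 0.02 ps (202 ps total), a 2-mm beam
raster-scanned at 1-mm steps over a 12 x 12 mm^2 field of view, a 96-dB
peak spectral dynamic range and 4.5 THz of usable bandwidth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Tuple

import yaml


class InvalidConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class AcquisitionConfig:
    """Time axis and instrument-level parameters of a simulated scan.

    ``dt_ps * n_samples`` is the trace duration; the defaults give 202 ps so
    that a 650-sample pulse window spans exactly 13 ps.  ``t_metal_ps`` fixes
    the arrival time of the echo from the bare metal holder plane, which
    serves as the global time reference for all other echoes.
    """

    dt_ps: float = 0.02
    n_samples: int = 10_100
    noise_dynamic_range_db: Optional[float] = 96.0
    beam_diameter_mm: float = 2.0
    step_mm: float = 1.0
    f_max_thz: float = 4.5
    t_metal_ps: float = 80.0

    def validate(self) -> None:
        if self.dt_ps <= 0:
            raise InvalidConfigError("dt_ps must be positive")
        if self.n_samples < 650:
            raise InvalidConfigError("n_samples must be at least 650")
        if self.f_max_thz <= 0:
            raise InvalidConfigError("f_max_thz must be positive")
        if self.beam_diameter_mm <= 0 or self.step_mm <= 0:
            raise InvalidConfigError("beam/step geometry must be positive")

    @property
    def duration_ps(self) -> float:
        return self.dt_ps * self.n_samples


@dataclass
class ExtractionConfig:
    """Pulse detection and segmentation parameters.

    The 8% relative threshold and the 650-sample minimum separation follow
    the standard configuration for resolving distinct reflections in a
    202-ps trace; 650 samples is also the segment window (13 ps).
    """

    rel_threshold: float = 0.08
    min_sep_samples: int = 650
    window_samples: int = 650
    max_pulses_per_pixel: int = 8

    def validate(self) -> None:
        if not 0.0 < self.rel_threshold < 1.0:
            raise InvalidConfigError("rel_threshold must lie in (0, 1)")
        if self.min_sep_samples < 1 or self.window_samples < 1:
            raise InvalidConfigError("separation/window must be positive")
        if self.max_pulses_per_pixel < 1:
            raise InvalidConfigError("max_pulses_per_pixel must be >= 1")


@dataclass
class LabelConfig:
    """Training-label generation parameters.

    ``edge_factor`` scales the bulk amplitude quantile to obtain the
    material-specific edge threshold; ``threshold_margin`` keeps that
    threshold strictly above the global detection threshold even for
    degenerate amplitude distributions.
    """

    arrival_tolerance_samples: Optional[int] = None  # None -> derived from spread
    edge_quantile: float = 0.5
    edge_factor: float = 0.6
    threshold_margin: float = 0.25

    def validate(self) -> None:
        if not 0.0 < self.edge_quantile < 1.0:
            raise InvalidConfigError("edge_quantile must lie in (0, 1)")
        if self.edge_factor <= 0:
            raise InvalidConfigError("edge_factor must be positive")


@dataclass
class ClassNetConfig:
    """Per-pulse CNN classifier: two conv/ReLU/max-pool stages and two
    fully connected layers ending in a 9-way softmax (8 chemicals plus
    the metal background)."""

    conv1: Tuple[int, int] = (16, 9)  # (channels, kernel)
    conv2: Tuple[int, int] = (32, 9)
    pool: int = 2
    hidden: int = 128
    n_classes: int = 9
    input_len: int = 650


@dataclass
class EdgeNetConfig:
    """Per-pixel set transformer for edge detection.

    Four pre-norm encoder blocks with eight attention heads operate on the
    pixel's padded 8 x 650 pulse stack.  No positional encoding is ever
    added and features are mean-pooled over the sequence axis, so the
    network is exactly permutation invariant in its pulse rows.
    """

    d_model: int = 128
    n_layers: int = 4
    n_heads: int = 8
    mlp_dim: int = 256
    n_classes: int = 2
    input_len: int = 650
    set_size: int = 8


@dataclass
class TrainConfig:
    """Optimization setup: Adam at lr 1e-3, batch 64, 200 epochs."""

    lr: float = 1e-3
    epochs: int = 200
    batch: int = 64
    seed: int = 0
    split_fraction: float = 0.2
    balanced: bool = True
    samples_per_class: int = 256  # per epoch when balanced sampling is on

    def validate(self) -> None:
        if self.lr <= 0 or self.batch < 1 or self.epochs < 1:
            raise InvalidConfigError("invalid optimizer settings")
        if not 0.0 <= self.split_fraction < 1.0:
            raise InvalidConfigError("split_fraction must lie in [0, 1)")


@dataclass
class FusionConfig:
    """Decision fusion and spatial post-processing parameters."""

    prob_threshold: float = 0.95
    vote_window: int = 3
    connectivity: int = 8
    min_component: int = 3
    aggregation: str = "max"  # "max" (winner-takes-all) or "mean"

    def validate(self) -> None:
        if not 0.0 < self.prob_threshold < 1.0:
            raise InvalidConfigError("prob_threshold must lie in (0, 1)")
        if self.aggregation not in ("max", "mean"):
            raise InvalidConfigError("aggregation must be 'max' or 'mean'")
        if self.connectivity not in (4, 8):
            raise InvalidConfigError("connectivity must be 4 or 8")


@dataclass
class RunConfig:
    """Bundle of every stage configuration plus the master seed."""

    seed: int = 0
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    labeling: LabelConfig = field(default_factory=LabelConfig)
    classnet: ClassNetConfig = field(default_factory=ClassNetConfig)
    edgenet: EdgeNetConfig = field(default_factory=EdgeNetConfig)
    classnet_train: TrainConfig = field(default_factory=TrainConfig)
    edgenet_train: TrainConfig = field(default_factory=TrainConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)

    def validate(self) -> None:
        self.acquisition.validate()
        self.extraction.validate()
        self.labeling.validate()
        self.classnet_train.validate()
        self.edgenet_train.validate()
        self.fusion.validate()


# ---------------------------------------------------------------------------
# serialization helpers


def to_dict(cfg) -> dict:
    """Recursively convert a (nested) config dataclass to plain dicts."""
    return dataclasses.asdict(cfg)


def config_hash(cfg) -> str:
    """Stable short hash of a config, for run records and output stamping."""
    payload = json.dumps(to_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _from_dict(cls, d: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            v = _from_dict(f.type, v)
        kwargs[f.name] = v
    return cls(**kwargs)


_SECTION_TYPES = {
    "acquisition": AcquisitionConfig,
    "extraction": ExtractionConfig,
    "labeling": LabelConfig,
    "classnet": ClassNetConfig,
    "edgenet": EdgeNetConfig,
    "classnet_train": TrainConfig,
    "edgenet_train": TrainConfig,
    "fusion": FusionConfig,
}


def run_config_from_dict(d: dict) -> RunConfig:
    kwargs = {}
    for key, val in d.items():
        if key in _SECTION_TYPES:
            sub = dict(val)
            if key in ("classnet", "edgenet"):
                for tup_key in ("conv1", "conv2"):
                    if tup_key in sub:
                        sub[tup_key] = tuple(sub[tup_key])
            kwargs[key] = _SECTION_TYPES[key](**sub)
        elif key == "seed":
            kwargs[key] = int(val)
    return RunConfig(**kwargs)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = run_config_from_dict(data)
    cfg.validate()
    return cfg


def save_run_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh, sort_keys=False)
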