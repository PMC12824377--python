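"""Material fingerprints and the class-code registry.

A :class:`MaterialSpec` describes a chemical's terahertz optical response
with a frequency-independent real refractive index plus a Lorentzian
absorption-line model,

    alpha(nu) = alpha_0 + sum_j A_j * gamma_j^2 / ((nu - nu_j)^2 + gamma_j^2)

with ``nu`` in THz and ``alpha`` in 1/cm.  The default registry holds
synthetic fingerprints for the eight screening targets (four pharmaceutical
excipients and four energetic materials).  The line positions and strengths
are illustrative constants chosen to be pairwise distinguishable below
4.5 THz; they are not measured optical constants of the named compounds.

Class codes: 0..7 chemicals, 8 background (bare metal holder), 9 edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

BACKGROUND = 8
EDGE = 9
N_CHEMICALS = 8
N_CLASSNET_CLASSES = 9  # chemicals + background

CLASS_NAMES = {
    0: "DCP",
    1: "MCC",
    2: "IBU",
    3: "MAN",
    4: "KNO3",
    5: "PETN",
    6: "RDX",
    7: "TNT",
    BACKGROUND: "background",
    EDGE: "edge",
}

#: class indices of the energetic (explosive) materials
EXPLOSIVE_CLASSES = (4, 5, 6, 7)


@dataclass(frozen=True)
class MaterialSpec:
    """Terahertz response of one chemical.

    ``lines`` is a sequence of ``(center_thz, halfwidth_thz, strength_cm)``
    Lorentzian triples; ``baseline_alpha`` is a flat absorption floor in
    1/cm.
    """

    name: str
    class_index: int
    n_refr: float
    lines: Tuple[Tuple[float, float, float], ...] = ()
    baseline_alpha: float = 0.0

    def __post_init__(self):
        if self.n_refr <= 0:
            raise ValueError(f"{self.name}: refractive index must be positive")
        if not 0 <= self.class_index <= BACKGROUND:
            raise ValueError(f"{self.name}: class_index out of range")
        object.__setattr__(self, "lines", tuple(tuple(l) for l in self.lines))

    def alpha(self, freqs_thz: np.ndarray) -> np.ndarray:
        """Absorption coefficient in 1/cm on the given frequency grid."""
        f = np.asarray(freqs_thz, dtype=float)
        a = np.full_like(f, float(self.baseline_alpha))
        for nu0, gamma, strength in self.lines:
            a = a + strength * gamma**2 / ((f - nu0) ** 2 + gamma**2)
        return a

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "class_index": self.class_index,
            "n_refr": self.n_refr,
            "lines": [list(l) for l in self.lines],
            "baseline_alpha": self.baseline_alpha,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialSpec":
        return cls(
            name=d["name"],
            class_index=int(d["class_index"]),
            n_refr=float(d["n_refr"]),
            lines=tuple(tuple(l) for l in d.get("lines", ())),
            baseline_alpha=float(d.get("baseline_alpha", 0.0)),
        )


def _registry(materials: Sequence[MaterialSpec]) -> Dict[str, MaterialSpec]:
    reg: Dict[str, MaterialSpec] = {}
    seen_idx = set()
    for m in materials:
        if m.class_index in seen_idx:
            raise ValueError(f"duplicate class index {m.class_index}")
        seen_idx.add(m.class_index)
        reg[m.name] = m
    return reg


# Synthetic default fingerprints (pairwise distinct line sets, centers well
# inside the 4.5-THz band, >= 2 resolution bins apart between materials).
DEFAULT_MATERIALS: Dict[str, MaterialSpec] = _registry(
    [
        MaterialSpec("DCP", 0, 1.90, ((0.95, 0.09, 7.0), (2.60, 0.12, 6.0)), 0.45),
        MaterialSpec("MCC", 1, 1.55, ((1.45, 0.10, 7.0),), 0.35),
        MaterialSpec("IBU", 2, 1.60, ((1.05, 0.08, 8.0), (1.85, 0.10, 6.0)), 0.40),
        MaterialSpec("MAN", 3, 1.65, ((1.65, 0.09, 8.0), (3.10, 0.14, 5.0)), 0.30),
        MaterialSpec("KNO3", 4, 1.80, ((2.00, 0.10, 9.0),), 0.50),
        MaterialSpec("PETN", 5, 1.70, ((1.25, 0.08, 5.0), (2.30, 0.11, 8.0)), 0.40),
        MaterialSpec(
            "RDX", 6, 1.75, ((0.82, 0.07, 8.0), (1.50, 0.09, 5.0), (3.00, 0.12, 5.0)), 0.55
        ),
        MaterialSpec("TNT", 7, 1.68, ((1.70, 0.10, 6.0), (2.45, 0.12, 7.0)), 0.35),
    ]
)


def material_by_class(class_index: int,
                      registry: Dict[str, MaterialSpec] | None = None) -> MaterialSpec:
    registry = registry if registry is not None else DEFAULT_MATERIALS
    for m in registry.values():
        if m.class_index == class_index:
            return m
    raise KeyError(f"no material with class index {class_index}")


def class_registry_dict() -> dict:
    """JSON/YAML-serializable class-code registry."""
    return {int(k): v for k, v in CLASS_NAMES.items()}
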