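"""Physics-based synthetic waveform generator for reflection-mode THz-TDS.

A scene is a metal holder plane with dielectric sample disks on it,
optionally concealed under a thin paper-like cover layer.  Each raster
pixel's time-domain trace is synthesized in the frequency domain as a sum
of delayed echo "rays" convolved with a band-limited reference pulse:

* ``P1`` -- Fresnel reflection off the sample top surface,
* ``P2`` -- reflection off the bare metal plane (modelled as r = -1),
  visible where the 2-mm beam footprint is not fully on a sample,
* ``P3`` -- reflection off the sample/metal bottom interface after one
  round trip through the sample (Beer-Lambert loss exp(-alpha*d) per
  one-way pass, propagation delay 2*n*d/c),
* ``P4``... -- Fabry-Perot internal round trips, truncated at K terms,
* an optional extra leading reflection from the 0.18-mm cover layer.

Edge pixels (partial beam overlap with a disk) receive an extra
multiplicative scattering loss on the sample rays, emulating the weak
boundary signals of a real scan.  White Gaussian noise is calibrated so a
background pixel's peak spectral dynamic range matches the configured dB
value.  All randomness derives from the scene seed through per-pixel
``SeedSequence`` spawn keys, so cubes are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import h5py
import numpy as np
import yaml

from .config import AcquisitionConfig, InvalidConfigError, to_dict
from .materials import (
    BACKGROUND,
    DEFAULT_MATERIALS,
    EDGE,
    EXPLOSIVE_CLASSES,
    MaterialSpec,
    class_registry_dict,
    material_by_class,
)

#: speed of light in mm/ps
C_MM_PS = 0.299792458

#: arrival time of the reference-pulse peak within its own window (ps)
REF_T0_PS = 3.0


class SceneError(ValueError):
    """Raised for invalid scene geometry (e.g. overlapping placements)."""


# ---------------------------------------------------------------------------
# reference pulse


def reference_sigma_ps(f_max_thz: float) -> float:
    """Gaussian width such that the pulse spectrum is < 1% of its peak at
    ``f_max``.  The Ricker amplitude spectrum f^2 exp(-(2 pi sigma f)^2/2)
    peaks at 2 pi sigma f* = sqrt(2); sigma = 2/(pi f_max) puts f_max at
    2 pi sigma f = 4, where the spectrum has decayed to ~0.7% of its
    peak."""
    return 2.0 / (np.pi * f_max_thz)


def make_reference_pulse(acq: AcquisitionConfig, t0_ps: float = REF_T0_PS) -> np.ndarray:
    """Band-limited single-cycle transient with a unique unit-amplitude
    extremum exactly at ``t0_ps``, so echo arrival times equal ray delays
    plus ``t0_ps``.

    A Ricker (Gaussian second-derivative) shape is used: it is zero-mean
    (no DC leakage), its side lobes are well below the central lobe
    (0.45x), and -- unlike the bipolar first derivative -- its global
    |amplitude| maximum is unique, which keeps peak detection unambiguous
    to within one sample."""
    acq.validate()
    sigma = reference_sigma_ps(acq.f_max_thz)
    duration = acq.duration_ps
    if t0_ps - 5 * sigma < 0 or t0_ps + 5 * sigma > duration:
        raise InvalidConfigError(
            f"reference pulse at t0={t0_ps} ps does not fit in a "
            f"{duration:.2f}-ps window"
        )
    t = np.arange(acq.n_samples) * acq.dt_ps
    u = (t - t0_ps) / sigma
    g = (1.0 - u**2) * np.exp(-(u**2) / 2.0)
    return g / np.max(np.abs(g))


_REF_CACHE: dict = {}


def _reference_spectrum(acq: AcquisitionConfig, n_pad: int) -> Tuple[np.ndarray, np.ndarray]:
    """rfft of the reference pulse on a zero-padded grid.  Returns
    (freqs_thz, spectrum); memoized on the time-axis parameters."""
    key = (acq.dt_ps, n_pad, acq.f_max_thz)
    if key not in _REF_CACHE:
        padded = replace(acq, n_samples=n_pad)
        ref = make_reference_pulse(padded, t0_ps=REF_T0_PS)
        freqs = np.fft.rfftfreq(n_pad, d=acq.dt_ps)  # cycles/ps == THz
        _REF_CACHE[key] = (freqs, np.fft.rfft(ref))
    return _REF_CACHE[key]


# ---------------------------------------------------------------------------
# layered-stack echo expansion


@dataclass(frozen=True)
class Ray:
    """One echo of the layered reflection response.

    ``delay_ps`` is relative to the sample top-surface echo; ``coeff`` is
    the frequency-independent Fresnel amplitude product; ``sample_passes``
    counts one-way passes through the sample for Beer-Lambert loss.
    """

    delay_ps: float
    coeff: float
    sample_passes: int


@dataclass(frozen=True)
class CoverSpec:
    """Thin dielectric concealment layer (paper-like) above the scene.

    ``standoff_mm`` is the height of the cover's top face above the metal
    plane; ``scatter`` is the specular-loss factor of its rough surface.
    """

    thickness_mm: float = 0.18
    n_refr: float = 1.5
    alpha: float = 6.0  # 1/cm, flat
    standoff_mm: float = 7.0
    scatter: float = 0.6

    @property
    def transit_extra_delay_ps(self) -> float:
        """Extra double-pass delay added to everything beneath the cover."""
        return 2.0 * (self.n_refr - 1.0) * self.thickness_mm / C_MM_PS

    @property
    def transmission(self) -> float:
        """Amplitude factor for one double pass through the cover."""
        n = self.n_refr
        t2 = 4.0 * n / (1.0 + n) ** 2
        return t2 * np.exp(-2.0 * self.alpha * self.thickness_mm / 10.0)

    def rays_rel_metal(self) -> List[Tuple[float, float]]:
        """Cover echo as (delay relative to the metal-plane echo, coeff).

        The cover contributes one extra leading reflection (its top face);
        the internal second-face echo of real fibrous paper is suppressed
        by scattering and is not modelled."""
        n = self.n_refr
        r_top = (1.0 - n) / (1.0 + n)
        lead = -2.0 * self.standoff_mm / C_MM_PS
        return [(lead, self.scatter * r_top)]


def complex_index(material: MaterialSpec, freqs_thz: np.ndarray) -> np.ndarray:
    """Complex refractive index n + i kappa with the extinction derived
    from the absorption model, kappa = c * alpha / (4 pi nu).

    The real part stays frequency-independent (no dispersion model); the
    imaginary part gives the surface reflection its material-specific
    spectral structure, so top-surface echoes are not all identical
    scaled copies of the reference pulse.  Frequencies below 0.05 THz are
    clipped to avoid the 1/nu singularity (the reference pulse carries no
    energy there)."""
    f = np.asarray(freqs_thz, dtype=float)
    fsafe = np.maximum(f, 0.05)
    kappa = C_MM_PS * (material.alpha(f) / 10.0) / (4.0 * np.pi * fsafe)
    return material.n_refr + 1j * kappa


def _fresnel_factors(ncplx: np.ndarray):
    """(r01, r10, t01*t10) field coefficients of the air/sample interface."""
    r01 = (1.0 - ncplx) / (1.0 + ncplx)
    return r01, -r01, 4.0 * ncplx / (1.0 + ncplx) ** 2


def sample_stack_rays(material: MaterialSpec, thickness_mm: float, k_round_trips: int = 3
                      ) -> List[Ray]:
    """Echo expansion of air / sample / metal at normal incidence, with
    real (kappa = 0) Fresnel coefficients.

    Ray 0 is the surface reflection (P1); ray k >= 1 is the k-th internal
    round trip terminating at the metal floor (P3, P4, ...).  Waveform
    synthesis itself uses the complex-index coefficients; this real-valued
    expansion gives the delays and leading-order amplitudes used by the
    timing oracles."""
    if material.n_refr <= 0:
        raise SceneError("non-physical material: n_refr must be positive")
    if thickness_mm <= 0:
        raise SceneError("thickness must be positive")
    n = material.n_refr
    r01 = (1.0 - n) / (1.0 + n)
    r10 = -r01
    t_prod = 4.0 * n / (1.0 + n) ** 2
    r_metal = -1.0
    round_trip_ps = 2.0 * n * thickness_mm / C_MM_PS
    rays = [Ray(0.0, r01, 0)]
    for k in range(1, k_round_trips + 1):
        coeff = t_prod * r_metal * (r10 * r_metal) ** (k - 1)
        rays.append(Ray(k * round_trip_ps, coeff, 2 * k))
    return rays


def stack_transfer_function(material: MaterialSpec, thickness_mm: float,
                            covered: bool, freqs_thz: np.ndarray,
                            k_round_trips: int = 3,
                            cover: CoverSpec | None = None,
                            cover_gap_mm: float = 4.0) -> np.ndarray:
    """Complex reflection response of the air/sample/metal stack.

    Time reference: the sample top-surface echo sits at delay 0, so the
    cover echoes (when ``covered``) appear at negative delay.  The phase
    convention matches ``numpy.fft``: a delay tau multiplies by
    exp(-2i pi f tau)."""
    f = np.asarray(freqs_thz, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequencies must be non-negative")
    d_cm = thickness_mm / 10.0
    alpha = material.alpha(f)
    H = np.zeros(f.shape, dtype=complex)
    trans = 1.0
    extra = 0.0
    cov = cover or CoverSpec()
    if covered:
        trans = cov.transmission
        extra = cov.transit_extra_delay_ps
        lead = -2.0 * cover_gap_mm / C_MM_PS
        n_c = cov.n_refr
        r_top = (1.0 - n_c) / (1.0 + n_c)
        H += cov.scatter * r_top * np.exp(-2j * np.pi * f * lead)
    if material.n_refr <= 0:
        raise SceneError("non-physical material: n_refr must be positive")
    if thickness_mm <= 0:
        raise SceneError("thickness must be positive")
    r01, r10, t_prod = _fresnel_factors(complex_index(material, f))
    round_trip_ps = 2.0 * material.n_refr * thickness_mm / C_MM_PS
    for k in range(k_round_trips + 1):
        coeff = r01 if k == 0 else t_prod * (-1.0) * (r10 * -1.0) ** (k - 1)
        amp = trans * coeff * np.exp(-alpha * d_cm * 2 * k)
        H += amp * np.exp(-2j * np.pi * f * (k * round_trip_ps + extra))
    return H


# ---------------------------------------------------------------------------
# scene geometry


@dataclass(frozen=True)
class Placement:
    """One sample disk: material name, disk center in mm (x, y), diameter
    and thickness in mm."""

    material: str
    center_mm: Tuple[float, float]
    diameter_mm: float = 10.0
    thickness_mm: float = 3.0


@dataclass
class SceneSpec:
    grid_shape: Tuple[int, int] = (13, 13)  # (ny, nx)
    placements: Tuple[Placement, ...] = ()
    covered: bool = False
    cover: CoverSpec = field(default_factory=CoverSpec)
    crack_masks: Tuple[frozenset, ...] = ()
    crack_attenuation: float = 0.45
    crack_jitter_ps: float = 0.1
    edge_band: Tuple[float, float] = (0.05, 0.85)
    edge_scatter: Tuple[float, float] = (0.4, 0.6)
    # per-pixel surface-height / thickness tolerance of a pressed pellet
    # (~+-7.5 um), randomizing the sub-sample phase of each echo
    surface_jitter_mm: float = 0.0075
    thickness_jitter_mm: float = 0.0075
    k_round_trips: int = 3
    seed: int = 0

    def __post_init__(self):
        self.placements = tuple(self.placements)
        self.crack_masks = tuple(frozenset(tuple(p) for p in m) for m in self.crack_masks)

    def validate(self, registry: Dict[str, MaterialSpec] | None = None) -> None:
        registry = registry if registry is not None else DEFAULT_MATERIALS
        for p in self.placements:
            if p.material not in registry:
                raise SceneError(f"unknown material {p.material!r}")
            if not 0 < p.thickness_mm:
                raise SceneError("thickness must be positive")
        for i, a in enumerate(self.placements):
            for b in self.placements[i + 1:]:
                dist = np.hypot(a.center_mm[0] - b.center_mm[0],
                                a.center_mm[1] - b.center_mm[1])
                if dist < (a.diameter_mm + b.diameter_mm) / 2.0:
                    raise SceneError(
                        f"overlapping placements {a.material}/{b.material}")
        lo, hi = self.edge_band
        if not 0.0 <= lo < hi <= 1.0:
            raise SceneError("edge_band must satisfy 0 <= lo < hi <= 1")


def disk_beam_overlap(dist_mm: float, beam_radius_mm: float, disk_radius_mm: float) -> float:
    """Area fraction of a circular beam footprint covered by a disk
    (classic circle-circle lens formula)."""
    r, R, d = beam_radius_mm, disk_radius_mm, dist_mm
    if d >= r + R:
        return 0.0
    if d <= abs(R - r):
        return 1.0 if R >= r else (R / r) ** 2
    alpha = np.arccos(np.clip((d * d + r * r - R * R) / (2 * d * r), -1, 1))
    beta = np.arccos(np.clip((d * d + R * R - r * r) / (2 * d * R), -1, 1))
    lens = (r * r * alpha + R * R * beta
            - 0.5 * np.sqrt(max((-d + r + R) * (d + r - R) * (d - r + R) * (d + r + R), 0.0)))
    return float(lens / (np.pi * r * r))


def overlap_fractions(scene: SceneSpec, acq: AcquisitionConfig,
                      iy: int, ix: int) -> np.ndarray:
    """Beam-overlap fraction of pixel (iy, ix) with each placement."""
    x = ix * acq.step_mm
    y = iy * acq.step_mm
    beam_r = acq.beam_diameter_mm / 2.0
    out = np.zeros(len(scene.placements))
    for i, p in enumerate(scene.placements):
        dist = np.hypot(x - p.center_mm[0], y - p.center_mm[1])
        out[i] = disk_beam_overlap(dist, beam_r, p.diameter_mm / 2.0)
    return out


def ground_truth_maps(scene: SceneSpec, acq: AcquisitionConfig,
                      registry: Dict[str, MaterialSpec] | None = None
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """(class_map, material_map) ground truth grids.

    A pixel is the chemical when its dominant overlap fraction reaches the
    upper edge-band bound, an edge inside the transition band, and
    background otherwise.  ``material_map`` records the underlying chemical
    index wherever any overlap exists (-1 elsewhere)."""
    registry = registry if registry is not None else DEFAULT_MATERIALS
    ny, nx = scene.grid_shape
    cls = np.full((ny, nx), BACKGROUND, dtype=np.int64)
    mat = np.full((ny, nx), -1, dtype=np.int64)
    lo, hi = scene.edge_band
    for iy in range(ny):
        for ix in range(nx):
            fr = overlap_fractions(scene, acq, iy, ix)
            if fr.size == 0 or fr.max() <= 0.0:
                continue
            k = int(np.argmax(fr))
            code = registry[scene.placements[k].material].class_index
            mat[iy, ix] = code
            f = fr[k]
            if f >= hi:
                cls[iy, ix] = code
            elif f > lo:
                cls[iy, ix] = EDGE
    return cls, mat


# ---------------------------------------------------------------------------
# pixel and scene synthesis


def pixel_rng(scene_seed: int, iy: int, ix: int) -> np.random.Generator:
    """Deterministic per-pixel random stream derived from the scene seed."""
    return np.random.default_rng(np.random.SeedSequence(scene_seed, spawn_key=(iy, ix)))


def _in_crack(scene: SceneSpec, iy: int, ix: int) -> bool:
    return any((iy, ix) in m for m in scene.crack_masks)


def background_peak_spectrum(scene: SceneSpec, acq: AcquisitionConfig) -> float:
    """Peak amplitude-spectrum magnitude of a noiseless bare-metal pixel
    (through the cover if the scene is covered); the reference level for
    dynamic-range noise calibration."""
    trace = _synthesize(scene, acq, fractions=np.zeros(len(scene.placements)),
                        edge_factor=1.0, crack=False, rng=None)
    return float(np.abs(np.fft.rfft(trace)).max())


def noise_sigma(scene: SceneSpec, acq: AcquisitionConfig) -> float:
    """Per-sample white-noise std giving the configured peak spectral
    dynamic range on a background pixel.  The noise floor is the RMS
    per-bin magnitude sigma * sqrt(N)."""
    db = acq.noise_dynamic_range_db
    if db is None or not np.isfinite(db):
        return 0.0
    s_max = background_peak_spectrum(scene, acq)
    return s_max / (np.sqrt(acq.n_samples) * 10.0 ** (db / 20.0))


def _synthesize(scene: SceneSpec, acq: AcquisitionConfig, fractions: np.ndarray,
                edge_factor: float, crack: bool,
                rng: Optional[np.random.Generator],
                registry: Dict[str, MaterialSpec] | None = None) -> np.ndarray:
    """Noiseless frequency-domain assembly of one pixel's trace."""
    registry = registry if registry is not None else DEFAULT_MATERIALS
    import scipy.fft

    n_pad = scipy.fft.next_fast_len(2 * acq.n_samples)
    freqs, R = _reference_spectrum(acq, n_pad)
    H = np.zeros(freqs.shape, dtype=complex)

    trans = scene.cover.transmission if scene.covered else 1.0
    extra = scene.cover.transit_extra_delay_ps if scene.covered else 0.0

    f_tot = float(np.clip(fractions.sum(), 0.0, 1.0))
    # bare-metal echo from the uncovered part of the footprint
    if f_tot < 1.0:
        H += (1.0 - f_tot) * (-1.0) * trans * np.exp(
            -2j * np.pi * freqs * (acq.t_metal_ps + extra))
    # sample-stack echoes per placement
    for frac, p in zip(fractions, scene.placements):
        if frac <= 0.0:
            continue
        material = registry[p.material]
        dz = dd = 0.0
        if rng is not None:
            if scene.surface_jitter_mm > 0:
                dz = rng.uniform(-scene.surface_jitter_mm, scene.surface_jitter_mm)
            if scene.thickness_jitter_mm > 0:
                dd = rng.uniform(-scene.thickness_jitter_mm, scene.thickness_jitter_mm)
        d_px = p.thickness_mm + dd
        d_cm = d_px / 10.0
        alpha = material.alpha(freqs)
        r01, r10, t_prod = _fresnel_factors(complex_index(material, freqs))
        tau_surface = acq.t_metal_ps - 2.0 * (d_px + dz) / C_MM_PS
        jitter = 0.0
        amp_scale = frac * edge_factor * trans
        if crack:
            amp_scale *= scene.crack_attenuation
            if rng is not None and scene.crack_jitter_ps > 0:
                jitter = rng.uniform(-scene.crack_jitter_ps, scene.crack_jitter_ps)
        round_trip_ps = 2.0 * material.n_refr * d_px / C_MM_PS
        for k in range(scene.k_round_trips + 1):
            if k == 0:
                coeff = r01
            else:
                coeff = t_prod * (-1.0) * (r10 * -1.0) ** (k - 1)
            amp = amp_scale * coeff * np.exp(-alpha * d_cm * 2 * k)
            tau = tau_surface + k * round_trip_ps + extra + jitter
            H += amp * np.exp(-2j * np.pi * freqs * tau)
    # cover doublet (covers the whole field of view)
    if scene.covered:
        for dly, coeff in scene.cover.rays_rel_metal():
            H += coeff * np.exp(-2j * np.pi * freqs * (acq.t_metal_ps + dly))
    trace = np.fft.irfft(R * H, n=n_pad)[: acq.n_samples]
    return trace


def simulate_pixel(scene: SceneSpec, pixel: Tuple[int, int], acq: AcquisitionConfig,
                   rng: Optional[np.random.Generator] = None,
                   sigma: Optional[float] = None,
                   registry: Dict[str, MaterialSpec] | None = None) -> np.ndarray:
    """Simulate one pixel's time-domain trace.

    ``rng`` defaults to the pixel's seeded stream; ``sigma`` (noise std) is
    computed from the scene dynamic range when not supplied."""
    iy, ix = pixel
    ny, nx = scene.grid_shape
    if not (0 <= iy < ny and 0 <= ix < nx):
        raise IndexError(f"pixel {pixel} outside grid {scene.grid_shape}")
    if rng is None:
        rng = pixel_rng(scene.seed, iy, ix)
    fractions = overlap_fractions(scene, acq, iy, ix)
    f_tot = float(np.clip(fractions.sum(), 0.0, 1.0))
    lo, hi = scene.edge_band
    edge_factor = 1.0
    if lo < f_tot < hi:
        edge_factor = float(rng.uniform(*scene.edge_scatter))
    crack = _in_crack(scene, iy, ix)
    trace = _synthesize(scene, acq, fractions, edge_factor, crack, rng, registry)
    if sigma is None:
        sigma = noise_sigma(scene, acq)
    if sigma > 0:
        trace = trace + rng.normal(0.0, sigma, size=trace.shape)
    return trace


# ---------------------------------------------------------------------------
# waveform cube container


@dataclass
class WaveformCube:
    """Raster-scanned cube of time-domain traces with acquisition metadata."""

    field: np.ndarray  # [ny, nx, n_samples]
    acq: AcquisitionConfig
    ground_truth: Optional[np.ndarray] = None  # [ny, nx] class codes
    material_map: Optional[np.ndarray] = None
    provenance: dict = None

    @property
    def grid_shape(self) -> Tuple[int, int]:
        return self.field.shape[0], self.field.shape[1]

    def save_h5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("field", data=self.field.astype(np.float64))
            ds.attrs["dt_ps"] = self.acq.dt_ps
            ds.attrs["step_mm"] = self.acq.step_mm
            db = self.acq.noise_dynamic_range_db
            ds.attrs["noise_dynamic_range_db"] = np.inf if db is None else db
            ds.attrs["f_max_thz"] = self.acq.f_max_thz
            ds.attrs["beam_diameter_mm"] = self.acq.beam_diameter_mm
            ds.attrs["t_metal_ps"] = self.acq.t_metal_ps
            ds.attrs["seed"] = (self.provenance or {}).get("seed", -1)
            ds.attrs["class_registry"] = json.dumps(class_registry_dict())
            if self.ground_truth is not None:
                fh.create_dataset("ground_truth", data=self.ground_truth.astype(np.int64))
            if self.material_map is not None:
                fh.create_dataset("material_map", data=self.material_map.astype(np.int64))
            if self.provenance:
                fh.attrs["provenance"] = json.dumps(self.provenance, default=str)

    @classmethod
    def load_h5(cls, path) -> "WaveformCube":
        with h5py.File(path, "r") as fh:
            ds = fh["field"]
            db = float(ds.attrs["noise_dynamic_range_db"])
            acq = AcquisitionConfig(
                dt_ps=float(ds.attrs["dt_ps"]),
                n_samples=ds.shape[2],
                noise_dynamic_range_db=None if np.isinf(db) else db,
                step_mm=float(ds.attrs["step_mm"]),
                f_max_thz=float(ds.attrs.get("f_max_thz", 4.5)),
                beam_diameter_mm=float(ds.attrs.get("beam_diameter_mm", 2.0)),
                t_metal_ps=float(ds.attrs.get("t_metal_ps", 80.0)),
            )
            gt = fh["ground_truth"][...] if "ground_truth" in fh else None
            mm = fh["material_map"][...] if "material_map" in fh else None
            prov = json.loads(fh.attrs["provenance"]) if "provenance" in fh.attrs else None
            return cls(ds[...], acq, gt, mm, prov)

    def save_npz(self, path) -> None:
        db = self.acq.noise_dynamic_range_db
        np.savez(
            path,
            field=self.field,
            dt_ps=self.acq.dt_ps,
            step_mm=self.acq.step_mm,
            noise_dynamic_range_db=np.inf if db is None else db,
            f_max_thz=self.acq.f_max_thz,
            beam_diameter_mm=self.acq.beam_diameter_mm,
            t_metal_ps=self.acq.t_metal_ps,
            seed=(self.provenance or {}).get("seed", -1),
            ground_truth=self.ground_truth if self.ground_truth is not None else np.array([]),
            material_map=self.material_map if self.material_map is not None else np.array([]),
        )

    @classmethod
    def load_npz(cls, path) -> "WaveformCube":
        z = np.load(path)
        db = float(z["noise_dynamic_range_db"])
        acq = AcquisitionConfig(
            dt_ps=float(z["dt_ps"]),
            n_samples=z["field"].shape[2],
            noise_dynamic_range_db=None if np.isinf(db) else db,
            step_mm=float(z["step_mm"]),
            f_max_thz=float(z["f_max_thz"]),
            beam_diameter_mm=float(z["beam_diameter_mm"]),
            t_metal_ps=float(z["t_metal_ps"]),
        )
        gt = z["ground_truth"] if z["ground_truth"].size else None
        mm = z["material_map"] if z["material_map"].size else None
        return cls(z["field"], acq, gt, mm, {"seed": int(z["seed"])})


def scene_to_dict(scene: SceneSpec) -> dict:
    return {
        "grid_shape": list(scene.grid_shape),
        "placements": [
            {"material": p.material, "center_mm": list(p.center_mm),
             "diameter_mm": p.diameter_mm, "thickness_mm": p.thickness_mm}
            for p in scene.placements
        ],
        "covered": scene.covered,
        "cover": to_dict(scene.cover),
        "crack_masks": [sorted(list(m)) for m in scene.crack_masks],
        "crack_attenuation": scene.crack_attenuation,
        "crack_jitter_ps": scene.crack_jitter_ps,
        "edge_band": list(scene.edge_band),
        "edge_scatter": list(scene.edge_scatter),
        "surface_jitter_mm": scene.surface_jitter_mm,
        "thickness_jitter_mm": scene.thickness_jitter_mm,
        "k_round_trips": scene.k_round_trips,
        "seed": scene.seed,
        "class_registry": class_registry_dict(),
    }


def scene_from_dict(d: dict) -> SceneSpec:
    return SceneSpec(
        grid_shape=tuple(d.get("grid_shape", (13, 13))),
        placements=tuple(
            Placement(p["material"], tuple(p["center_mm"]),
                      float(p.get("diameter_mm", 10.0)), float(p["thickness_mm"]))
            for p in d.get("placements", ())
        ),
        covered=bool(d.get("covered", False)),
        cover=CoverSpec(**d["cover"]) if "cover" in d else CoverSpec(),
        crack_masks=tuple(frozenset(tuple(px) for px in m)
                          for m in d.get("crack_masks", ())),
        crack_attenuation=float(d.get("crack_attenuation", 0.45)),
        crack_jitter_ps=float(d.get("crack_jitter_ps", 0.1)),
        edge_band=tuple(d.get("edge_band", (0.05, 0.85))),
        edge_scatter=tuple(d.get("edge_scatter", (0.4, 0.6))),
        surface_jitter_mm=float(d.get("surface_jitter_mm", 0.0075)),
        thickness_jitter_mm=float(d.get("thickness_jitter_mm", 0.0075)),
        k_round_trips=int(d.get("k_round_trips", 3)),
        seed=int(d.get("seed", 0)),
    )


def load_scene(path) -> SceneSpec:
    with open(path) as fh:
        return scene_from_dict(yaml.safe_load(fh))


def save_scene(scene: SceneSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scene_to_dict(scene), fh, sort_keys=False)


def simulate_scene(scene: SceneSpec, acq: AcquisitionConfig,
                   registry: Dict[str, MaterialSpec] | None = None) -> WaveformCube:
    """Simulate the full raster scan of a scene, with ground truth."""
    acq.validate()
    scene.validate(registry)
    ny, nx = scene.grid_shape
    sigma = noise_sigma(scene, acq)
    field_arr = np.empty((ny, nx, acq.n_samples))
    for iy in range(ny):
        for ix in range(nx):
            field_arr[iy, ix] = simulate_pixel(
                scene, (iy, ix), acq, sigma=sigma, registry=registry)
    gt, mat = ground_truth_maps(scene, acq, registry)
    prov = {"scene": scene_to_dict(scene), "seed": scene.seed}
    return WaveformCube(field_arr, acq, gt, mat, prov)


# ---------------------------------------------------------------------------
# analytic echo timing (oracle helpers)


def echo_delays_ps(material: MaterialSpec, thickness_mm: float,
                   acq: AcquisitionConfig, k_round_trips: int = 3) -> Dict[str, float]:
    """Analytic arrival times (ps, including the reference-pulse offset) of
    the echo taxonomy for an interior/edge pixel over a sample of the given
    thickness."""
    t_surface = acq.t_metal_ps - 2.0 * thickness_mm / C_MM_PS + REF_T0_PS
    rt = 2.0 * material.n_refr * thickness_mm / C_MM_PS
    out = {"P1": t_surface, "P2": acq.t_metal_ps + REF_T0_PS}
    for k in range(1, k_round_trips + 1):
        out[f"P{k + 2}"] = t_surface + k * rt
    return out


def echo_indices(material: MaterialSpec, thickness_mm: float,
                 acq: AcquisitionConfig, k_round_trips: int = 3) -> Dict[str, float]:
    """Echo arrival times expressed in (fractional) sample indices."""
    return {k: v / acq.dt_ps
            for k, v in echo_delays_ps(material, thickness_mm, acq, k_round_trips).items()}


# ---------------------------------------------------------------------------
# benchmark scene collections


@dataclass
class BenchmarkConfig:
    """Train/test scene-collection protocol.

    Concealed (covered) and cracked variants are blind-test only; requesting
    them in the training split is rejected, mirroring the
    train-on-visible / test-on-concealed generalization protocol."""

    train_scenes_per_class: int = 2
    test_scenes_per_class: int = 1
    covered_test: bool = True
    cracked_test_scenes: int = 0
    train_covered: bool = False
    train_cracked: bool = False
    base_seed: int = 0
    grid_shape: Tuple[int, int] = (13, 13)
    diameter_mm: float = 10.0
    thickness_range_mm: Tuple[float, float] = (2.0, 4.0)
    center_jitter_mm: float = 0.7
    train_seed_offset: int = 1000
    test_seed_offset: int = 2000
    covered_seed_offset: int = 3000
    cracked_seed_offset: int = 4000


@dataclass
class BenchmarkPlan:
    train: List[SceneSpec]
    test_uncovered: List[SceneSpec]
    test_covered: List[SceneSpec]
    test_cracked: List[SceneSpec]

    def all_seeds(self) -> Dict[str, List[int]]:
        return {
            "train": [s.seed for s in self.train],
            "test_uncovered": [s.seed for s in self.test_uncovered],
            "test_covered": [s.seed for s in self.test_covered],
            "test_cracked": [s.seed for s in self.test_cracked],
        }


def make_disk_scene(material_name: str, seed: int, grid_shape=(13, 13),
                    diameter_mm: float = 10.0,
                    thickness_range_mm=(2.0, 4.0), center_jitter_mm: float = 0.7,
                    covered: bool = False, cracked: bool = False) -> SceneSpec:
    """One centered (jittered) disk of a single chemical."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(17,)))
    ny, nx = grid_shape
    cx = (nx - 1) / 2.0 + rng.uniform(-center_jitter_mm, center_jitter_mm)
    cy = (ny - 1) / 2.0 + rng.uniform(-center_jitter_mm, center_jitter_mm)
    thickness = float(rng.uniform(*thickness_range_mm))
    placement = Placement(material_name, (cx, cy), diameter_mm, thickness)
    masks: Tuple[frozenset, ...] = ()
    if cracked:
        col = int(round(cx)) + int(rng.integers(-1, 2))
        rows = range(max(0, int(round(cy)) - 3), min(ny, int(round(cy)) + 4))
        masks = (frozenset((iy, col) for iy in rows),)
    return SceneSpec(grid_shape=grid_shape, placements=(placement,),
                     covered=covered, crack_masks=masks, seed=seed)


def make_benchmark(cfg: BenchmarkConfig,
                   registry: Dict[str, MaterialSpec] | None = None) -> BenchmarkPlan:
    """Build disjoint-seed train/test scene collections for all chemicals."""
    registry = registry if registry is not None else DEFAULT_MATERIALS
    if cfg.train_covered:
        raise SceneError("covered scenes are test-only (blind generalization protocol)")
    if cfg.train_cracked:
        raise SceneError("cracked scenes are test-only (blind generalization protocol)")
    offsets = [cfg.train_seed_offset, cfg.test_seed_offset,
               cfg.covered_seed_offset, cfg.cracked_seed_offset]
    spans = [cfg.train_scenes_per_class * 8, cfg.test_scenes_per_class * 8,
             8, max(cfg.cracked_test_scenes, 0)]
    ranges = [set(range(cfg.base_seed + o, cfg.base_seed + o + s))
              for o, s in zip(offsets, spans)]
    for i in range(len(ranges)):
        for j in range(i + 1, len(ranges)):
            if ranges[i] & ranges[j]:
                raise SceneError("benchmark seed ranges overlap")

    chem_names = [material_by_class(c, registry).name for c in range(8)]
    train, test_unc, test_cov, test_crk = [], [], [], []
    t_lo, t_hi = cfg.thickness_range_mm
    n_rep = cfg.train_scenes_per_class
    for rep in range(n_rep):
        # training thicknesses are stratified so each class's samples span
        # the full 2-4 mm range (the study conditions); test thicknesses
        # are drawn from the whole range
        stratum = (t_lo + (t_hi - t_lo) * rep / n_rep,
                   t_lo + (t_hi - t_lo) * (rep + 1) / n_rep)
        for c, name in enumerate(chem_names):
            seed = cfg.base_seed + cfg.train_seed_offset + rep * 8 + c
            train.append(make_disk_scene(name, seed, cfg.grid_shape, cfg.diameter_mm,
                                         stratum, cfg.center_jitter_mm))
    for rep in range(cfg.test_scenes_per_class):
        for c, name in enumerate(chem_names):
            seed = cfg.base_seed + cfg.test_seed_offset + rep * 8 + c
            test_unc.append(make_disk_scene(name, seed, cfg.grid_shape, cfg.diameter_mm,
                                            cfg.thickness_range_mm, cfg.center_jitter_mm))
    if cfg.covered_test:
        for i, c in enumerate(EXPLOSIVE_CLASSES):
            name = material_by_class(c, registry).name
            seed = cfg.base_seed + cfg.covered_seed_offset + i
            test_cov.append(make_disk_scene(name, seed, cfg.grid_shape, cfg.diameter_mm,
                                            cfg.thickness_range_mm, cfg.center_jitter_mm,
                                            covered=True))
    for i in range(cfg.cracked_test_scenes):
        name = chem_names[i % 8]
        seed = cfg.base_seed + cfg.cracked_seed_offset + i
        test_crk.append(make_disk_scene(name, seed, cfg.grid_shape, cfg.diameter_mm,
                                        cfg.thickness_range_mm, cfg.center_jitter_mm,
                                        cracked=True))
    train_seeds = {s.seed for s in train}
    for s in test_unc + test_cov + test_crk:
        if s.seed in train_seeds:
            raise SceneError("test seed collides with a training seed")
    return BenchmarkPlan(train, test_unc, test_cov, test_crk)
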