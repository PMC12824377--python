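"""Absorption-spectrum diagnostics from pulse pairs.

A 650-sample (13-ps) segment transforms to a one-sided amplitude spectrum
with bin spacing 1/(650 * 0.02 ps) = 76.92 GHz.  The material absorbance
follows from the bottom-interface echo P3 referenced to the holder echo
P2: A(nu) = -ln(|S3|/|S2|), evaluated only where |S2| stays above a
spectral floor.  No Fresnel or thickness normalization is applied, so A is
a dimensionless attenuation measure whose local maxima sit at the
material's absorption-line centers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple
import warnings

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .config import AcquisitionConfig


@dataclass
class Spectrum:
    freqs_ghz: np.ndarray
    values: np.ndarray
    resolution_ghz: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"freq_ghz": self.freqs_ghz, "value": self.values})

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def save_png(self, path, ylabel: str = "amplitude / absorbance") -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(self.freqs_ghz / 1000.0, self.values)
        ax.set_xlabel("frequency (THz)")
        ax.set_ylabel(ylabel)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def pulse_spectrum(samples: np.ndarray, acq: AcquisitionConfig) -> Spectrum:
    """One-sided amplitude spectrum of a pulse segment."""
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    freqs_thz = np.fft.rfftfreq(n, d=acq.dt_ps)
    amp = np.abs(np.fft.rfft(samples))
    resolution_ghz = 1000.0 / (n * acq.dt_ps)
    return Spectrum(freqs_thz * 1000.0, amp, resolution_ghz)


def absorbance(p3_samples: np.ndarray, p2_samples: np.ndarray,
               acq: AcquisitionConfig,
               band_thz: Tuple[float, float] = (0.2, 4.5),
               floor_fraction: float = 0.01) -> Spectrum:
    """Absorbance A(nu) = -ln(|S3|/|S2|) over the band, restricted to bins
    where |S2| exceeds ``floor_fraction`` of its peak."""
    s3 = pulse_spectrum(p3_samples, acq)
    s2 = pulse_spectrum(p2_samples, acq)
    lo, hi = (b * 1000.0 for b in band_thz)
    floor = floor_fraction * s2.values.max()
    mask = (s2.freqs_ghz >= lo) & (s2.freqs_ghz <= hi) & (s2.values > floor)
    if not mask.any():
        raise ValueError("reference spectrum below floor across the whole band")
    a = -np.log(s3.values[mask] / s2.values[mask])
    return Spectrum(s2.freqs_ghz[mask], a, s2.resolution_ghz)


def recover_line_centers(spec: Spectrum, k: int,
                         prominence: float = 0.3) -> List[float]:
    """Frequencies (GHz) of the k most prominent absorbance maxima, sorted
    by frequency.  Returns fewer with a warning when fewer peaks exist."""
    if k < 1:
        raise ValueError("k must be >= 1")
    idx, props = find_peaks(spec.values, prominence=prominence)
    if idx.size == 0:
        return []
    order = np.argsort(props["prominences"])[::-1][:k]
    centers = sorted(float(spec.freqs_ghz[i]) for i in idx[order])
    if len(centers) < k:
        warnings.warn(f"only {len(centers)} of {k} requested peaks found")
    return centers
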