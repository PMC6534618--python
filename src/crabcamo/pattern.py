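"""Granularity pattern-energy spectra and the pattern energy difference.

Pattern is quantified on the luminance (avian double-cone) image by
band-pass filtering at octave-spaced spatial scales in the Fourier domain
and recording the standard deviation of the filtered pixels in a region of
interest ("pattern energy") per scale band. Two patterns with similar
energy at every scale give a small pattern energy difference (PED, the sum
of absolute energy differences), indicating pattern background matching;
deviation in either amplitude or shape of the spectra inflates it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_SQRT2 = math.sqrt(2.0)


def default_scales(min_dim: int, largest: int = 256) -> list[float]:
    """Octave scale series 2, 4, ... px, capped at ``largest`` and at half
    the smallest image dimension."""
    scales = []
    s = 2.0
    while s <= min(largest, min_dim / 2):
        scales.append(s)
        s *= 2.0
    if not scales:
        raise ValueError(f"image of min dimension {min_dim} too small")
    return scales


@dataclass
class PatternSpectrum:
    """Pattern energy (std of band-passed luminance) per spatial scale."""

    scales: np.ndarray
    energies: np.ndarray

    def __post_init__(self):
        self.scales = np.asarray(self.scales, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")
        if np.any(self.energies < 0):
            raise ValueError("energies must be non-negative")

    def total_energy(self) -> float:
        return float(self.energies.sum())


def _band_masks(shape: tuple[int, int], scales: list[float]) -> list[np.ndarray]:
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    r = np.hypot(fy, fx)
    with np.errstate(divide="ignore"):
        period = np.where(r > 0, 1.0 / r, np.inf)
    # snap adjacent band edges so an octave series tiles the spectrum
    # without double-counting boundary frequencies to rounding error
    edges = [(s / _SQRT2, s * _SQRT2) for s in scales]
    for i in range(1, len(edges)):
        lo, hi = edges[i]
        prev_hi = edges[i - 1][1]
        if abs(lo - prev_hi) <= 1e-9 * prev_hi:
            edges[i] = (prev_hi, hi)
    return [(period >= lo) & (period < hi) for lo, hi in edges]


def bandpass_stack(lum: np.ndarray, scales: list[float]) -> list[np.ndarray]:
    """Annular Fourier band-pass at each scale.

    Band ``s`` keeps spatial periods in [s/√2, s·√2); consecutive octave
    scales therefore tile the spectrum without overlap. The image mean is
    removed first; the operator is linear.
    """
    lum = np.asarray(lum, dtype=float)
    if max(scales) > min(lum.shape) / 2:
        raise ValueError(
            f"largest scale {max(scales)} exceeds half the smallest image "
            f"dimension ({min(lum.shape) / 2})")
    F = np.fft.fft2(lum - lum.mean())
    return [np.real(np.fft.ifft2(F * m))
            for m in _band_masks(lum.shape, scales)]


def granularity_spectrum(lum: np.ndarray, roi: np.ndarray,
                         scales: list[float]) -> PatternSpectrum:
    """Pattern energy spectrum of ``roi``.

    Pixels outside the ROI are filled with the ROI mean before the transform
    (mean fill avoids the spurious edge energy a zero fill would inject);
    each band's energy is the standard deviation of the filtered pixels
    inside the ROI.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    lum = np.asarray(lum, dtype=float)
    filled = np.where(roi, lum, lum[roi].mean())
    bands = bandpass_stack(filled, scales)
    energies = [float(b[roi].std()) for b in bands]
    return PatternSpectrum(scales=np.asarray(scales), energies=np.asarray(energies))


def ped(a: PatternSpectrum, b: PatternSpectrum) -> float:
    """Pattern energy difference: Σ_s |E_a(s) − E_b(s)|.

    Energies are deliberately not normalised, so both amplitude and shape
    mismatches between the spectra register.
    """
    if a.scales.shape != b.scales.shape or np.any(a.scales != b.scales):
        raise ValueError("pattern spectra use different scale series")
    return float(np.abs(a.energies - b.energies).sum())


def mean_ped_to_habitat(crab_spectrum: PatternSpectrum,
                        background_spectra: list[PatternSpectrum]) -> float:
    """Arithmetic mean PED of one crab against a habitat's backgrounds."""
    if not background_spectra:
        raise ValueError("need at least one background spectrum")
    return float(np.mean([ped(crab_spectrum, s) for s in background_spectra]))
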