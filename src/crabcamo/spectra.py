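"""Spectral grid, reflectance spectra and camera/receptor response rendering.

Everything spectral in this package lives on a single fixed wavelength grid
(300–700 nm in 5 nm steps, covering the UV-A window down to 300 nm that the
UV photography channel needs). Reflectance spectra are unitless fractions in
[0, 1]; sensitivities are non-negative and need not be normalised because
cone catches are computed as illuminant-normalised quotients.
"""

from __future__ import annotations

import numpy as np

#: Fixed wavelength grid in nm (inclusive, 5 nm steps).
WAVELENGTHS = np.arange(300.0, 701.0, 5.0)

#: Trapezoid quadrature weights for the grid (nm).
_TRAP_W = np.full(WAVELENGTHS.size, 5.0)
_TRAP_W[0] = _TRAP_W[-1] = 2.5


def check_on_grid(spectrum: np.ndarray, name: str = "spectrum") -> np.ndarray:
    """Validate that ``spectrum``'s last axis matches the wavelength grid."""
    arr = np.asarray(spectrum, dtype=float)
    if arr.shape[-1] != WAVELENGTHS.size:
        raise ValueError(
            f"{name} has {arr.shape[-1]} samples; expected "
            f"{WAVELENGTHS.size} on the 300-700 nm / 5 nm grid"
        )
    return arr


def flat_illuminant() -> np.ndarray:
    """Equal-energy illuminant (overcast-sky stand-in), unit spectral power."""
    return np.ones_like(WAVELENGTHS)


def gaussian_band(peak: float, sigma: float,
                  support: tuple[float, float] | None = None) -> np.ndarray:
    """Gaussian sensitivity band peaking at ``peak`` nm.

    ``support`` optionally truncates the band to a wavelength interval
    (sensitivity is zero outside), as for interference-filtered camera
    channels with hard cut-offs.
    """
    s = np.exp(-0.5 * ((WAVELENGTHS - peak) / sigma) ** 2)
    if support is not None:
        lo, hi = support
        s = np.where((WAVELENGTHS >= lo) & (WAVELENGTHS <= hi), s, 0.0)
    if s.max() <= 0:
        raise ValueError("sensitivity band is identically zero on the grid")
    return s / s.max()


class CameraModel:
    """Named camera channel sensitivities on the common grid.

    The default emulates a UV-converted DSLR shot through visible-pass and
    UV-pass filters: four channels (UV, SW, MW, LW) with peaks at
    380/460/540/625 nm and hard filter cut-offs.
    """

    def __init__(self, channels: dict[str, np.ndarray]):
        if not channels:
            raise ValueError("camera needs at least one channel")
        self.channels = {}
        for name, s in channels.items():
            s = check_on_grid(s, f"channel {name!r}")
            if np.any(s < 0):
                raise ValueError(f"channel {name!r} has negative sensitivity")
            self.channels[name] = s

    @classmethod
    def default(cls) -> "CameraModel":
        return cls({
            "UV": gaussian_band(380.0, 15.0, support=(360.0, 400.0)),
            "SW": gaussian_band(460.0, 40.0, support=(400.0, 550.0)),
            "MW": gaussian_band(540.0, 45.0, support=(420.0, 620.0)),
            "LW": gaussian_band(625.0, 40.0, support=(560.0, 700.0)),
        })

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def sensitivity_matrix(self) -> np.ndarray:
        """(n_channels, n_wavelengths) stacked sensitivities."""
        return np.stack([self.channels[n] for n in self.channels])

    def peak_wavelengths(self) -> dict[str, float]:
        return {n: float(WAVELENGTHS[np.argmax(s)])
                for n, s in self.channels.items()}


def normalized_catches(reflectance: np.ndarray, sensitivities: np.ndarray,
                       illuminant: np.ndarray | None = None) -> np.ndarray:
    """Illuminant-normalised quantum catches.

    catch_c = ∫ R(λ) I(λ) S_c(λ) dλ / ∫ I(λ) S_c(λ) dλ  (trapezoid rule),
    so a spectrally flat reflector of reflectance r yields catch r in every
    channel, and the catch is linear in the reflectance spectrum.

    Parameters
    ----------
    reflectance : (..., n_wavelengths)
    sensitivities : (n_channels, n_wavelengths)
    illuminant : (n_wavelengths,), defaults to equal energy.

    Returns
    -------
    (..., n_channels) array of unitless catches.
    """
    R = check_on_grid(reflectance, "reflectance")
    S = check_on_grid(sensitivities, "sensitivities")
    if S.ndim != 2:
        raise ValueError("sensitivities must be 2-D (channels x wavelengths)")
    I = flat_illuminant() if illuminant is None else check_on_grid(illuminant, "illuminant")
    weighted = S * I * _TRAP_W            # (c, w)
    denom = weighted.sum(axis=1)          # (c,)
    if np.any(denom <= 0):
        raise ValueError("a channel has zero integrated illuminant catch")
    return R @ weighted.T / denom
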