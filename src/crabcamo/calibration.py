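"""Image calibration against black/white reflectance standards.

Field photographs carry a two-patch sintered-PTFE standard (8.2% and 94.8%
reflectance across the spectrum) in one corner. Calibration maps raw linear
channel values onto percent reflectance per channel by the affine transform
anchored at the two standard means, and resamples images to a common spatial
scale (px/mm). Synthetic renders are already linear, so no separate
linearisation step is applied here; the normalisation seam is where
camera-specific linearised RAW data would enter for real photographs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

#: Spectrally flat reflectances of the two standard patches, percent.
BLACK_STANDARD_PCT = 8.2
WHITE_STANDARD_PCT = 94.8


@dataclass
class MultispectralImage:
    """Named co-registered 2-D channel rasters with a spatial scale.

    ``channels`` values are unitless (raw catches) before calibration and
    percent reflectance after :func:`normalize_to_reflectance`. All channels
    share one shape; ``masks`` are boolean rasters on the same grid.
    """

    channels: dict[str, np.ndarray]
    px_per_mm: float
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if not self.channels:
            raise ValueError("image needs at least one channel")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")
        for name, m in self.masks.items():
            if m.shape != self.shape:
                raise ValueError(f"mask {name!r} shape {m.shape} != {self.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def stack(self) -> np.ndarray:
        """(n_channels, H, W) view of the channels in declared order."""
        return np.stack([self.channels[n] for n in self.channels])


@dataclass
class StandardMeasurement:
    """Per-channel mean pixel values of the black and white standard patches."""

    black: dict[str, float]
    white: dict[str, float]

    def __post_init__(self):
        for name in self.black:
            if not self.white[name] > self.black[name]:
                raise ValueError(
                    f"invalid standard in channel {name!r}: white mean "
                    f"{self.white[name]!r} <= black mean {self.black[name]!r}"
                )


def measure_standards(img: MultispectralImage, black_mask: np.ndarray,
                      white_mask: np.ndarray) -> StandardMeasurement:
    """Arithmetic per-channel means over the two standard patches."""
    black_mask = np.asarray(black_mask, dtype=bool)
    white_mask = np.asarray(white_mask, dtype=bool)
    if not black_mask.any():
        raise ValueError("black standard mask is empty")
    if not white_mask.any():
        raise ValueError("white standard mask is empty")
    black = {n: float(c[black_mask].mean()) for n, c in img.channels.items()}
    white = {n: float(c[white_mask].mean()) for n, c in img.channels.items()}
    return StandardMeasurement(black=black, white=white)


def normalize_to_reflectance(img: MultispectralImage,
                             std: StandardMeasurement) -> MultispectralImage:
    """Affine map of each channel onto percent reflectance.

    A pixel at the black-standard mean maps to 8.2, at the white-standard
    mean to 94.8; values outside the standards' range extrapolate linearly
    and are deliberately not clipped (specular or shadowed pixels carry
    information downstream operators guard against themselves).
    """
    span = WHITE_STANDARD_PCT - BLACK_STANDARD_PCT
    out = {}
    for name, c in img.channels.items():
        b, w = std.black[name], std.white[name]
        out[name] = BLACK_STANDARD_PCT + (c - b) * (span / (w - b))
    return MultispectralImage(channels=out, px_per_mm=img.px_per_mm,
                              masks=dict(img.masks))


def rescale_to_resolution(img: MultispectralImage, target_px_per_mm: float,
                          allow_upscale: bool = False) -> MultispectralImage:
    """Resample all channels (and masks) to ``target_px_per_mm``.

    Downscaling only by default: inventing sub-pixel detail by upsampling is
    refused unless ``allow_upscale`` is set. Integer downscale factors use
    exact block averaging (mean-preserving); other factors use anti-aliased
    bilinear resampling. Masks are resampled nearest-neighbour.
    """
    if target_px_per_mm <= 0:
        raise ValueError("target_px_per_mm must be positive")
    factor = target_px_per_mm / img.px_per_mm
    if factor == 1.0:
        return MultispectralImage(
            channels={n: c.copy() for n, c in img.channels.items()},
            px_per_mm=img.px_per_mm,
            masks={n: m.copy() for n, m in img.masks.items()})
    if factor > 1.0 and not allow_upscale:
        raise ValueError(
            f"refusing to upscale from {img.px_per_mm} to {target_px_per_mm} "
            "px/mm; pass allow_upscale=True to override")

    h, w = img.shape
    inv = 1.0 / factor
    out_shape = (max(1, round(h * factor)), max(1, round(w * factor)))

    def _resample(c: np.ndarray) -> np.ndarray:
        if inv >= 1 and abs(inv - round(inv)) < 1e-12:
            k = int(round(inv))
            if h % k == 0 and w % k == 0:
                return c.reshape(h // k, k, w // k, k).mean(axis=(1, 3))
        return resize(c, out_shape, order=1, anti_aliasing=factor < 1.0,
                      preserve_range=True)

    channels = {n: _resample(c) for n, c in img.channels.items()}
    masks = {
        n: resize(m.astype(float), next(iter(channels.values())).shape,
                  order=0, anti_aliasing=False, preserve_range=True) > 0.5
        for n, m in img.masks.items()
    }
    return MultispectralImage(channels=channels, px_per_mm=target_px_per_mm,
                              masks=masks)
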