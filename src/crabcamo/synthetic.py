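"""Synthetic multispectral scenes with known reflectance ground truth.

This module emulates the study system end to end so that every downstream
stage (calibration, cone mapping, discrimination, pattern, edge disruption,
statistics) can be exercised against known truth without any field data:

* two background classes — low-contrast, homogeneous **mudflat** (dark brown
  mud with gentle large-scale variation) and high-contrast, multi-scale
  **rockpool** (rocks, pebbles, sand and algae patches tessellated across
  spatial scales);
* crab-shaped targets that are either **uniform** (background-matched, as
  mudflat juveniles tend to be) or **disruptive** (high-contrast blotches
  biased toward the carapace margin, as in rock-pool juveniles);
* embedded black/white reflectance standards (8.2% / 94.8%) in one corner of
  every scene, with a surrounding exclusion zone;
* a four-channel UV/SW/MW/LW camera with configurable peak wavelengths
  (defaults 380/460/540/625 nm).

Scenes are stored as a palette of reflectance spectra plus a per-pixel
palette-index raster, which keeps ground truth exact and rendering cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import MultispectralImage
from .spectra import (WAVELENGTHS, CameraModel, check_on_grid,
                      gaussian_band, normalized_catches)

#: Reflectance fractions of the embedded standards.
BLACK_STANDARD = 0.082
WHITE_STANDARD = 0.948

#: Default achromatic band used to calibrate scene RMS contrast; matches the
#: default avian double-cone stand-in in :mod:`crabcamo.vision`.
_DEFAULT_LUM_SENS = gaussian_band(560.0, 50.0)


# ---------------------------------------------------------------------------
# base reflectance spectra of the substrate materials

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def mud_spectrum() -> np.ndarray:
    """Dark brown intertidal mud: low overall, rising toward long wavelengths."""
    return np.clip(0.03 + 0.09 * _sigmoid((WAVELENGTHS - 580) / 60.0), 0.01, 0.99)


def sand_spectrum() -> np.ndarray:
    """Pale sand: bright, gently rising."""
    return np.clip(0.25 + 0.20 * _sigmoid((WAVELENGTHS - 500) / 90.0), 0.01, 0.99)


def rock_dark_spectrum() -> np.ndarray:
    return np.clip(0.08 + 0.03 * _sigmoid((WAVELENGTHS - 550) / 80.0), 0.01, 0.99)


def rock_light_spectrum() -> np.ndarray:
    return np.clip(0.30 + 0.05 * _sigmoid((WAVELENGTHS - 520) / 80.0), 0.01, 0.99)


def algae_spectrum() -> np.ndarray:
    """Green algae: chlorophyll-like bump around 550 nm."""
    bump = np.exp(-0.5 * ((WAVELENGTHS - 550) / 40.0) ** 2)
    tail = 0.10 * _sigmoid((WAVELENGTHS - 680) / 15.0)
    return np.clip(0.03 + 0.16 * bump + tail, 0.01, 0.99)


# ---------------------------------------------------------------------------
# parameter containers

@dataclass
class HabitatTextureParams:
    """Texture recipe for one background class.

    ``rms_contrast_target`` is the luminance RMS contrast (std/mean of the
    achromatic band) the generated texture is calibrated to hit (±20%).
    ``patch_scale_range`` bounds patch radii in px for the tessellation.
    """

    class_label: str
    patch_scale_range: tuple[float, float]
    rms_contrast_target: float
    base_spectra: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        if self.class_label not in ("mudflat", "rockpool"):
            raise ValueError("class_label must be 'mudflat' or 'rockpool'")
        lo, hi = self.patch_scale_range
        if lo <= 0 or hi < lo:
            raise ValueError("patch scales must be positive and ordered")
        if self.rms_contrast_target <= 0:
            raise ValueError("rms_contrast_target must be positive")
        self.base_spectra = [check_on_grid(s) for s in self.base_spectra]

    @classmethod
    def mudflat(cls) -> "HabitatTextureParams":
        return cls(class_label="mudflat", patch_scale_range=(16.0, 64.0),
                   rms_contrast_target=0.08, base_spectra=[mud_spectrum()])

    @classmethod
    def rockpool(cls) -> "HabitatTextureParams":
        return cls(class_label="rockpool", patch_scale_range=(3.0, 48.0),
                   rms_contrast_target=0.35,
                   base_spectra=[sand_spectrum(), rock_dark_spectrum(),
                                 rock_light_spectrum(), algae_spectrum()])


@dataclass
class CrabPhenotype:
    """Appearance recipe for one synthetic juvenile crab.

    ``edge_bias`` is the minimum fraction of total blotch area required to
    fall within the outer quartile of the distance-to-edge range, mimicking
    margin-biased disruptive markings. Carapace width is capped below 15 mm
    (juveniles only).
    """

    style: str
    base_spectrum: np.ndarray
    blotch_count: int = 0
    blotch_contrast: float = 0.0
    edge_bias: float = 0.8
    carapace_width: float = 8.0  # mm

    def __post_init__(self):
        if self.style not in ("uniform", "disruptive"):
            raise ValueError("style must be 'uniform' or 'disruptive'")
        if not self.carapace_width < 15:
            raise ValueError("carapace_width must be < 15 mm (juveniles)")
        if self.style == "uniform" and self.blotch_count != 0:
            raise ValueError("uniform style requires blotch_count == 0")
        if not 0 <= self.edge_bias <= 1:
            raise ValueError("edge_bias must be in [0, 1]")
        self.base_spectrum = check_on_grid(self.base_spectrum)


@dataclass
class Scene:
    """Palette-indexed reflectance scene plus masks and scale."""

    labels: np.ndarray            # (H, W) int palette indices
    spectra: np.ndarray           # (K, n_wavelengths) reflectance fractions
    masks: dict[str, np.ndarray]  # boolean rasters, mutually disjoint
    px_per_mm: float
    class_label: str = ""
    seed: int | None = None

    def __post_init__(self):
        self.spectra = check_on_grid(self.spectra)
        if self.labels.max() >= self.spectra.shape[0]:
            raise ValueError("label index out of palette range")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")
        total = np.zeros(self.labels.shape, dtype=int)
        for m in self.masks.values():
            total += m.astype(int)
        if total.max() > 1:
            raise ValueError("scene masks must be mutually disjoint")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def reflectance_stack(self) -> np.ndarray:
        """(H, W, n_wavelengths) dense ground-truth reflectance (large)."""
        return self.spectra[self.labels]

    def placement_exclusion(self) -> np.ndarray:
        """Union of standard patches and the exclusion corner."""
        out = np.zeros(self.shape, dtype=bool)
        for key in ("standard_white", "standard_black", "exclusion"):
            if key in self.masks:
                out |= self.masks[key]
        return out

    def usable(self) -> np.ndarray:
        """Pixels belonging to the substrate proper."""
        return ~self.placement_exclusion()


@dataclass
class CrabPatch:
    """A rendered crab target: carapace mask plus palette reflectance."""

    mask: np.ndarray              # (h, w) bool, carapace
    labels: np.ndarray            # (h, w) int palette indices (0 outside)
    spectra: np.ndarray           # (K, n_wavelengths)
    px_per_mm: float
    phenotype: CrabPhenotype

    def blotch_mask(self) -> np.ndarray:
        return self.mask & (self.labels > 0)

    def reflectance_stack(self) -> np.ndarray:
        return self.spectra[self.labels]


# ---------------------------------------------------------------------------
# spectrum library

def make_spectrum_library(n: int, seed: int) -> np.ndarray:
    """Random smooth reflectance spectra for training the cone mapping.

    Each spectrum is a constant base plus up to four Gaussian or sigmoidal
    components with broad widths, clipped to [0.01, 0.99]. Smooth,
    low-dimensional spectra mimic natural substrate reflectances and keep the
    camera→cone polynomial mapping well posed.

    Returns an (n, n_wavelengths) array; deterministic for a fixed seed.
    """
    if n < 2:
        raise ValueError("need at least 2 spectra to train a mapping")
    rng = np.random.default_rng(seed)
    out = np.empty((n, WAVELENGTHS.size))
    for i in range(n):
        s = np.full(WAVELENGTHS.size, rng.uniform(0.05, 0.55))
        for _ in range(rng.integers(1, 5)):
            amp = rng.uniform(-0.35, 0.45)
            centre = rng.uniform(320, 680)
            width = rng.uniform(40, 160)
            if rng.random() < 0.5:
                s = s + amp * np.exp(-0.5 * ((WAVELENGTHS - centre) / width) ** 2)
            else:
                s = s + amp * _sigmoid((WAVELENGTHS - centre) / (0.5 * width))
        out[i] = np.clip(s, 0.01, 0.99)
    return out


# ---------------------------------------------------------------------------
# backgrounds

def _luminance_of(spectra: np.ndarray, lum_sens: np.ndarray) -> np.ndarray:
    return normalized_catches(spectra, lum_sens[None, :])[:, 0]


def _calibrate_contrast(spectra: np.ndarray, labels: np.ndarray,
                        region: np.ndarray, target: float,
                        lum_sens: np.ndarray, n_iter: int = 6) -> np.ndarray:
    """Scale palette spectra about their area-weighted mean so the achromatic
    RMS contrast (std/mean) over ``region`` hits ``target``; clipping to the
    physical range is folded into the iteration."""
    counts = np.bincount(labels[region].ravel(), minlength=spectra.shape[0])
    w = counts / counts.sum()
    base = spectra.copy()
    scale = 1.0
    for _ in range(n_iter):
        mean_spec = (w[:, None] * base).sum(axis=0)
        cur = np.clip(mean_spec + scale * (base - mean_spec), 0.005, 0.995)
        lum = _luminance_of(cur, lum_sens)
        mu = (w * lum).sum()
        sd = math.sqrt(max((w * (lum - mu) ** 2).sum(), 0.0))
        achieved = sd / mu
        if abs(achieved - target) / target < 0.02:
            break
        scale *= target / max(achieved, 1e-9)
    return cur


def _place_standards(labels: np.ndarray, spectra: list[np.ndarray],
                     masks: dict[str, np.ndarray], px_per_mm: float,
                     standard_mm: float) -> list[np.ndarray]:
    """Burn the white/black standards into the top-left corner; returns the
    extended palette. Masks are filled in place and kept disjoint."""
    h, w = labels.shape
    sz = max(4, int(round(standard_mm * px_per_mm)))
    m = max(3, sz // 6)
    bar = max(10, sz)  # scale-bar allowance to the right of the patches
    if 2 * m + sz > h or 3 * m + 2 * sz + bar > w:
        raise ValueError(
            f"scene {h}x{w} too small to hold {sz}px standards with margins")
    white_idx = len(spectra)
    spectra.append(np.full(WAVELENGTHS.size, WHITE_STANDARD))
    black_idx = len(spectra)
    spectra.append(np.full(WAVELENGTHS.size, BLACK_STANDARD))

    white = np.zeros((h, w), dtype=bool)
    black = np.zeros((h, w), dtype=bool)
    white[m:m + sz, m:m + sz] = True
    black[m:m + sz, 2 * m + sz:2 * m + 2 * sz] = True
    corner = np.zeros((h, w), dtype=bool)
    corner[:2 * m + sz, :3 * m + 2 * sz + bar] = True

    labels[white] = white_idx
    labels[black] = black_idx
    masks["standard_white"] = white
    masks["standard_black"] = black
    masks["exclusion"] = corner & ~white & ~black
    return spectra


def make_background_scene(params: HabitatTextureParams,
                          size: tuple[int, int] = (512, 512),
                          seed: int = 0, px_per_mm: float = 10.0,
                          standard_mm: float = 5.0,
                          lum_sens: np.ndarray | None = None) -> Scene:
    """Generate one background scene of the requested habitat class.

    Mudflat scenes are a single mud spectrum modulated by smoothed
    low-amplitude noise; rockpool scenes are a multi-scale tessellation of
    rock/pebble/sand/algae patches. Both are calibrated so the achromatic
    RMS contrast of the substrate lands within ±20% of the class target, and
    both carry the corner reflectance standards and exclusion zone.
    """
    h, w = size
    if h < 256 or w < 256:
        raise ValueError("scene must be at least 256x256 px")
    if lum_sens is None:
        lum_sens = _DEFAULT_LUM_SENS
    rng = np.random.default_rng(seed)

    if params.class_label == "mudflat":
        labels, spectra = _mudflat_texture(params, (h, w), rng)
    else:
        labels, spectra = _rockpool_texture(params, (h, w), rng)

    masks: dict[str, np.ndarray] = {}
    region = np.ones((h, w), dtype=bool)
    spectra_arr = _calibrate_contrast(spectra, labels, region,
                                      params.rms_contrast_target, lum_sens)
    palette = list(spectra_arr)
    palette = _place_standards(labels, palette, masks, px_per_mm, standard_mm)
    return Scene(labels=labels, spectra=np.stack(palette), masks=masks,
                 px_per_mm=px_per_mm, class_label=params.class_label,
                 seed=seed)


def _mudflat_texture(params, size, rng):
    h, w = size
    n_levels = 33
    sigma = 0.5 * (params.patch_scale_range[0] + params.patch_scale_range[1]) / 2
    field_ = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma)
    field_ = (field_ - field_.mean()) / (field_.std() + 1e-12)
    # quantise the smooth field into palette levels of brightness factors
    edges = np.linspace(-3, 3, n_levels - 1)
    labels = np.digitize(field_, edges).astype(np.int32)
    centres = np.concatenate([[-3.2], 0.5 * (edges[:-1] + edges[1:]), [3.2]])
    base = params.base_spectra[0]
    spectra = np.clip(base[None, :] * (1.0 + 0.25 * centres[:, None]),
                      0.005, 0.995)
    return labels, spectra


def _rockpool_texture(params, size, rng):
    h, w = size
    lo, hi = params.patch_scale_range
    base_choices = params.base_spectra
    spectra = [base_choices[0]]          # palette 0: sand matrix
    labels = np.zeros((h, w), dtype=np.int32)

    # sample patch radii log-uniformly until overdraw covers the scene twice
    area_budget = 2.0 * h * w
    radii = []
    while area_budget > 0:
        r = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        radii.append(r)
        area_budget -= math.pi * r * r
    radii.sort(reverse=True)             # big rocks first, pebbles on top

    for r in radii:
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        spec = base_choices[rng.integers(0, len(base_choices))]
        jitter = math.exp(rng.normal(0.0, 0.25))
        spectra.append(np.clip(spec * jitter, 0.005, 0.995))
        idx = len(spectra) - 1
        y0, y1 = max(0, int(cy - r - 1)), min(h, int(cy + r + 2))
        x0, x1 = max(0, int(cx - r - 1)), min(w, int(cx + r + 2))
        if y0 >= y1 or x0 >= x1:
            continue
        ys = np.arange(y0, y1)[:, None] - cy
        xs = np.arange(x0, x1)[None, :] - cx
        disc = ys * ys + xs * xs <= r * r
        labels[y0:y1, x0:x1][disc] = idx
    return labels, np.stack(spectra)


# ---------------------------------------------------------------------------
# crabs

def _carapace_mask(width_px: int, rng: np.random.Generator) -> np.ndarray:
    """Smoothed ellipse with a scalloped anterior margin, star-shaped about
    its centre (hence connected and hole-free by construction)."""
    a = width_px / 2.0
    b = 0.40 * width_px
    pad = max(4, width_px // 8)
    side = width_px + 2 * pad
    cy = cx = side / 2.0 - 0.5
    ys = np.arange(side)[:, None] - cy
    xs = np.arange(side)[None, :] - cx
    re = np.sqrt((xs / a) ** 2 + (ys / b) ** 2)
    theta = np.arctan2(ys, xs)
    front = np.clip(-ys, 0, None) / (np.abs(ys) + np.abs(xs) + 1e-9)
    phase = rng.uniform(0, 2 * math.pi)
    scallop = 0.06 * np.cos(9 * theta + phase) * front
    return re <= 1.0 + scallop


def _draw_blotches(mask: np.ndarray, phenotype: CrabPhenotype,
                   rng: np.random.Generator, width_px: int,
                   max_retries: int = 25) -> np.ndarray:
    """Blotch label raster (0 none, 1 dark, 2 light) honouring the edge-bias
    contract: at least ``edge_bias`` of blotch area in the outer quartile of
    the distance-to-edge range."""
    dist = ndimage.distance_transform_edt(mask)
    maxd = dist.max()
    band = 0.25 * maxd
    outer_band = mask & (dist <= band)
    n = phenotype.blotch_count
    n_edge = math.ceil(phenotype.edge_bias * n)
    edge_pool = np.argwhere(mask & (dist > 0) & (dist <= 0.3 * band))
    core_pool = np.argwhere(dist > 1.5 * band)
    if len(edge_pool) == 0:
        raise ValueError("carapace too small for margin blotches")
    if len(core_pool) == 0:
        core_pool = edge_pool
    gy, gx = np.gradient(dist)

    for _ in range(max_retries):
        blotch = np.zeros(mask.shape, dtype=np.int8)
        for k in range(n):
            at_edge = k < n_edge
            pool = edge_pool if at_edge else core_pool
            cy, cx = pool[rng.integers(0, len(pool))]
            r = rng.uniform(0.04, 0.09) * width_px
            if at_edge:
                # margin blotches abut the outline and run across it: their
                # long, thin side edges cross the body margin (false
                # perpendicular edges) while the inward extent stays in the
                # outer band
                ang = math.atan2(gy[cy, cx], gx[cy, cx])
                ru = rng.uniform(0.6, 0.95) * band
                rv = max(1.5, rng.uniform(0.35, 0.7) * r)
            else:
                ang = rng.uniform(0, math.pi)
                ru = 0.5 * r * rng.uniform(1.0, 2.0)
                rv = 0.5 * r
            ys = np.arange(mask.shape[0])[:, None] - cy
            xs = np.arange(mask.shape[1])[None, :] - cx
            u = xs * math.cos(ang) + ys * math.sin(ang)
            v = -xs * math.sin(ang) + ys * math.cos(ang)
            ell = (u / ru) ** 2 + (v / rv) ** 2 <= 1.0
            blotch[ell & mask] = 1 + (k % 2)
        area = (blotch > 0).sum()
        if area == 0:
            continue
        frac = ((blotch > 0) & outer_band).sum() / area
        if frac >= phenotype.edge_bias:
            return blotch
    raise ValueError(
        f"could not place blotches with edge bias {phenotype.edge_bias} "
        f"after {max_retries} retries")


def make_crab(phenotype: CrabPhenotype, px_per_mm: float = 10.0,
              seed: int = 0) -> CrabPatch:
    """Generate a crab target (carapace mask + per-pixel reflectance).

    Uniform crabs carry their base spectrum everywhere; disruptive crabs add
    alternating dark/light blotches whose area is biased toward the margin.
    Blotch contrast ``c`` darkens toward ``base*(1-c)`` and brightens toward
    ``base + c*(0.9 - base)``.
    """
    width_px = int(round(phenotype.carapace_width * px_per_mm))
    if width_px < 16:
        raise ValueError("carapace must span at least 16 px at this scale")
    rng = np.random.default_rng(seed)
    mask = _carapace_mask(width_px, rng)

    base = phenotype.base_spectrum
    spectra = [base]
    labels = np.zeros(mask.shape, dtype=np.int32)
    if phenotype.style == "disruptive":
        c = phenotype.blotch_contrast
        spectra.append(np.clip(base * (1.0 - c), 0.005, 0.995))          # dark
        spectra.append(np.clip(base + c * (0.9 - base), 0.005, 0.995))   # light
        blotch = _draw_blotches(mask, phenotype, rng, width_px)
        labels[blotch > 0] = blotch[blotch > 0]
    return CrabPatch(mask=mask, labels=labels, spectra=np.stack(spectra),
                     px_per_mm=px_per_mm, phenotype=phenotype)


# ---------------------------------------------------------------------------
# rendering

def _render(labels: np.ndarray, spectra: np.ndarray,
            sensitivities: np.ndarray, illuminant: np.ndarray | None):
    catches = normalized_catches(spectra, sensitivities, illuminant)
    return catches[labels]  # (H, W, c)


def render_camera_image(scene: Scene, camera: CameraModel,
                        illuminant: np.ndarray | None = None) -> MultispectralImage:
    """Render a scene through the camera: illuminant-normalised channel
    catches (unitless; equals channel-weighted reflectance under the default
    flat illuminant). Linear in reflectance."""
    img = _render(scene.labels, scene.spectra, camera.sensitivity_matrix(),
                  illuminant)
    channels = {name: img[..., i] for i, name in enumerate(camera.channel_names)}
    return MultispectralImage(channels=channels, px_per_mm=scene.px_per_mm,
                              masks={k: v.copy() for k, v in scene.masks.items()})


def render_crab_camera_image(crab: CrabPatch, camera: CameraModel,
                             illuminant: np.ndarray | None = None) -> MultispectralImage:
    img = _render(crab.labels, crab.spectra, camera.sensitivity_matrix(),
                  illuminant)
    channels = {name: img[..., i] for i, name in enumerate(camera.channel_names)}
    return MultispectralImage(channels=channels, px_per_mm=crab.px_per_mm,
                              masks={"target": crab.mask.copy()})


def render_true_cone_catches(scene: Scene, visual_system,
                             illuminant: np.ndarray | None = None) -> MultispectralImage:
    """Ground-truth receptor catches straight from the reflectance spectra
    (used to train/validate the camera→cone mapping)."""
    sens = visual_system.sensitivity_matrix()
    img = _render(scene.labels, scene.spectra, sens, illuminant)
    channels = {name: img[..., i]
                for i, name in enumerate(visual_system.receptor_names)}
    return MultispectralImage(channels=channels, px_per_mm=scene.px_per_mm,
                              masks={k: v.copy() for k, v in scene.masks.items()})
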