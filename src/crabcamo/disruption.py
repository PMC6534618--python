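"""GabRat edge disruption with randomized non-overlapping target placement.

GabRat measures how strongly a target's outline is broken up: at every
pixel of the target outline, a quadrature pair of Gabor filters oriented
along the local outline tangent measures "coherent" edge energy (E_par),
and the pair oriented across the tangent measures "false" edge energy
(E_perp, texture edges crossing the outline). GabRat is the mean of
E_perp / (E_par + E_perp) over the outline: near 0 for a salient coherent
outline, above 0.5 when false edges dominate — i.e. highly disruptive.

To account for where a crab might sit in the wild, targets are composited
at seeded random positions on each background (disjoint from each other and
from exclusion zones) and GabRat is averaged over the placements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_EIGHT = np.ones((3, 3), dtype=int)

#: Samples with total Gabor energy below this are treated as featureless.
MIN_ENERGY = 1e-9


@dataclass
class GaborParams:
    """Quadrature Gabor filter bank parameters (px units).

    Defaults: sigma 3 px, wavelength 2·sigma·√2, isotropic envelope. The
    kernel half-width is 3 sigma.
    """

    sigma: float = 3.0
    wavelength: float = 3.0 * 2.0 * math.sqrt(2.0)
    aspect_ratio: float = 1.0

    def __post_init__(self):
        if self.sigma <= 0 or self.wavelength <= 0:
            raise ValueError("sigma and wavelength must be positive")

    @property
    def half_width(self) -> int:
        return int(math.ceil(3.0 * self.sigma))


@dataclass
class Placement:
    """Offset (row, col) of a target mask's origin on a background."""

    offset: tuple[int, int]


# ---------------------------------------------------------------------------
# outline extraction and tangents

def extract_outline(mask: np.ndarray) -> np.ndarray:
    """Ordered, closed boundary traversal of a connected mask.

    Moore-neighbour tracing with Jacob's stopping criterion; returns an
    (N, 2) array of (row, col) boundary pixels in traversal order (each
    adjacent to the next, last adjacent to first).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    n_comp = ndimage.label(mask, structure=_EIGHT)[1]
    if n_comp != 1:
        raise ValueError(f"mask has {n_comp} connected components, expected 1")

    padded = np.pad(mask, 1)
    start = tuple(np.argwhere(padded)[0])           # topmost-leftmost pixel
    # Moore neighbourhood in clockwise screen order, starting at "left"
    nbrs = ((0, -1), (-1, -1), (-1, 0), (-1, 1),
            (0, 1), (1, 1), (1, 0), (1, -1))
    cur, d = start, 4                               # as if entered moving right
    outline: list[tuple[int, int]] = []
    seen: dict[tuple, int] = {}
    while True:
        state = (cur, d)
        if state in seen:                           # closed the cycle
            outline = outline[seen[state]:]
            break
        seen[state] = len(outline)
        outline.append(cur)
        s = (d + 6) % 8                             # resume right of backtrack
        for k in range(8):
            dd = (s + k) % 8
            cand = (cur[0] + nbrs[dd][0], cur[1] + nbrs[dd][1])
            if padded[cand]:
                cur, d = cand, dd
                break
        else:
            break                                   # isolated single pixel
    return np.asarray(outline, dtype=int) - 1       # undo padding


def local_tangents(outline: np.ndarray, window: int = 7) -> np.ndarray:
    """Outline tangent angle at every boundary pixel, in [0, π).

    The tangent is the principal axis of the ``window`` boundary points
    centred (circularly) on each pixel — an orthogonal least-squares fit,
    well behaved for vertical edges. Angles are measured in (x=col, y=row)
    coordinates.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    n = len(outline)
    if n < window:
        raise ValueError(f"outline of {n} pixels shorter than window {window}")
    half = window // 2
    idx = (np.arange(n)[:, None] + np.arange(-half, half + 1)[None, :]) % n
    pts = outline[idx].astype(float)                 # (n, window, 2)
    pts -= pts.mean(axis=1, keepdims=True)
    y = pts[..., 0]
    x = pts[..., 1]
    sxx = (x * x).sum(axis=1)
    syy = (y * y).sum(axis=1)
    sxy = (x * y).sum(axis=1)
    ang = 0.5 * np.arctan2(2.0 * sxy, sxx - syy)
    return np.mod(ang, math.pi)


# ---------------------------------------------------------------------------
# Gabor energy

def _kernel_bank(thetas: np.ndarray, params: GaborParams):
    """Even/odd Gabor kernels per edge angle; carrier runs perpendicular to
    the edge orientation so the filter responds to edges at ``theta``.

    Returns (even, odd, envelope) arrays of shape (n, k, k), un-normalised;
    zero-meaning and normalisation happen per valid support at evaluation.
    """
    h = params.half_width
    off = np.arange(-h, h + 1, dtype=float)
    dy = off[:, None]
    dx = off[None, :]
    phi = thetas + math.pi / 2.0                     # modulation direction
    c = np.cos(phi)[:, None, None]
    s = np.sin(phi)[:, None, None]
    xp = dx * c + dy * s
    yp = -dx * s + dy * c
    g2 = params.aspect_ratio ** 2
    env = np.exp(-(xp ** 2 + g2 * yp ** 2) / (2.0 * params.sigma ** 2))
    arg = 2.0 * math.pi * xp / params.wavelength
    return env * np.cos(arg), env * np.sin(arg), env


def _energies(patches: np.ndarray, valid: np.ndarray, even: np.ndarray,
              odd: np.ndarray, env: np.ndarray) -> np.ndarray:
    """Quadrature energy per sample with border truncation handled by
    envelope-weighted zero-meaning and L2 renormalisation over the valid
    support."""
    ev = even * valid
    ov = odd * valid
    gv = env * valid
    gsum = gv.sum(axis=(1, 2))
    ez = ev - gv * (ev.sum(axis=(1, 2)) / gsum)[:, None, None]
    oz = ov - gv * (ov.sum(axis=(1, 2)) / gsum)[:, None, None]
    en = np.sqrt((ez * ez).sum(axis=(1, 2)))
    on = np.sqrt((oz * oz).sum(axis=(1, 2)))
    en[en == 0] = 1.0
    on[on == 0] = 1.0
    r_e = (patches * ez).sum(axis=(1, 2)) / en
    r_o = (patches * oz).sum(axis=(1, 2)) / on
    return np.hypot(r_e, r_o)


def _gather_patches(lum: np.ndarray, pts: np.ndarray, half: int):
    """Patches of side 2*half+1 around each point, with validity mask for
    out-of-image pixels (which read as 0)."""
    H, W = lum.shape
    off = np.arange(-half, half + 1)
    rows = pts[:, 0, None, None] + off[None, :, None]
    cols = pts[:, 1, None, None] + off[None, None, :]
    valid = (rows >= 0) & (rows < H) & (cols >= 0) & (cols < W)
    patches = lum[np.clip(rows, 0, H - 1), np.clip(cols, 0, W - 1)]
    return np.where(valid, patches, 0.0), valid.astype(float)


def gabor_energy(lum: np.ndarray, point: tuple[int, int], theta: float,
                 params: GaborParams | None = None) -> float:
    """Quadrature Gabor edge energy at one point for edge orientation
    ``theta``; invariant to a constant offset of the image."""
    params = params or GaborParams()
    pts = np.asarray([point])
    patches, valid = _gather_patches(np.asarray(lum, dtype=float), pts,
                                     params.half_width)
    even, odd, env = _kernel_bank(np.asarray([theta], dtype=float), params)
    return float(_energies(patches, valid, even, odd, env)[0])


# ---------------------------------------------------------------------------
# GabRat

class GabRatEngine:
    """Precomputed outline, tangents and kernel bank for one target mask.

    Re-used across the many random placements of the same crab, where only
    the underlying luminance values change.
    """

    def __init__(self, mask: np.ndarray, params: GaborParams | None = None,
                 window: int = 7):
        self.params = params or GaborParams()
        self.mask = np.asarray(mask, dtype=bool)
        self.outline = extract_outline(self.mask)
        self.tangents = local_tangents(self.outline, window)
        self._par = _kernel_bank(self.tangents, self.params)
        self._perp = _kernel_bank(self.tangents + math.pi / 2.0, self.params)

    def evaluate(self, lum: np.ndarray, offset: tuple[int, int] = (0, 0)) -> float:
        """GabRat of the outline placed at ``offset`` on luminance ``lum``
        (the target pixels of ``lum`` must already hold the target)."""
        pts = self.outline + np.asarray(offset, dtype=int)
        patches, valid = _gather_patches(np.asarray(lum, dtype=float), pts,
                                         self.params.half_width)
        e_par = _energies(patches, valid, *self._par)
        e_perp = _energies(patches, valid, *self._perp)
        total = e_par + e_perp
        keep = total >= MIN_ENERGY
        if not keep.any():
            warnings.warn("all outline samples featureless; GabRat set to 0")
            return 0.0
        return float((e_perp[keep] / total[keep]).mean())


def gabrat(lum: np.ndarray, mask: np.ndarray,
           params: GaborParams | None = None, window: int = 7) -> float:
    """GabRat of a target already present in ``lum`` under ``mask``.

    Mean over outline samples of E_perp/(E_par+E_perp); samples with total
    energy below ``MIN_ENERGY`` are skipped. Values lie in [0, 1]."""
    return GabRatEngine(mask, params, window).evaluate(lum)


# ---------------------------------------------------------------------------
# random placement and aggregation

def sample_placements(bg_shape: tuple[int, int], mask: np.ndarray, n: int,
                      exclusion: np.ndarray | None = None, seed: int = 0,
                      max_attempts: int | None = None) -> list[Placement]:
    """``n`` uniform random placements of ``mask`` on a background.

    Placements keep the full mask footprint inside the image, and are
    pairwise disjoint and disjoint from ``exclusion`` (rejection sampling,
    deterministic per seed). Raises if ``n`` cannot be placed within
    ``max_attempts`` (default 2000·n), reporting the achieved count.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    H, W = bg_shape
    h, w = mask.shape
    if h > H or w > W:
        raise ValueError("target larger than background")
    occupied = (np.zeros((H, W), dtype=bool) if exclusion is None
                else np.asarray(exclusion, dtype=bool).copy())
    rng = np.random.default_rng(seed)
    max_attempts = max_attempts or 2000 * n
    placements: list[Placement] = []
    for attempt in range(max_attempts):
        oy = int(rng.integers(0, H - h + 1))
        ox = int(rng.integers(0, W - w + 1))
        window_ = occupied[oy:oy + h, ox:ox + w]
        if window_[mask].any():
            continue
        window_[mask] = True
        placements.append(Placement(offset=(oy, ox)))
        if len(placements) == n:
            return placements
    raise RuntimeError(
        f"placed only {len(placements)} of {n} targets in {max_attempts} "
        "attempts; background too crowded")


def mean_gabrat(crab_lum: np.ndarray, crab_mask: np.ndarray,
                bg_lum: np.ndarray, n: int = 50,
                exclusion: np.ndarray | None = None,
                params: GaborParams | None = None, seed: int = 0,
                engine: GabRatEngine | None = None) -> tuple[float, list[float]]:
    """Average GabRat of one crab over ``n`` random placements on one
    background image. Returns (mean, per-placement values)."""
    crab_lum = np.asarray(crab_lum, dtype=float)
    bg_lum = np.asarray(bg_lum, dtype=float)
    crab_mask = np.asarray(crab_mask, dtype=bool)
    engine = engine or GabRatEngine(crab_mask, params)
    placements = sample_placements(bg_lum.shape, crab_mask, n,
                                   exclusion=exclusion, seed=seed)
    h, w = crab_mask.shape
    values = []
    for p in placements:
        oy, ox = p.offset
        window_ = bg_lum[oy:oy + h, ox:ox + w]
        saved = window_[crab_mask]
        window_[crab_mask] = crab_lum[crab_mask]
        values.append(engine.evaluate(bg_lum, offset=(oy, ox)))
        window_[crab_mask] = saved
    return float(np.mean(values)), values
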