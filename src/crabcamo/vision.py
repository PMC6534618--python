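"""Predator visual systems and the camera→cone-catch polynomial mapping.

Two default viewers are provided:

* ``peafowl`` — a violet-type tetrachromatic bird (UV/V, SW, MW, LW single
  cones for colour; double cone for luminance), the standard stand-in for
  shorebird predators;
* ``pollack`` — a dichromatic fish predator with SW and LW cones; its
  luminance channel is LW-based since fish lack double cones.

Receptor sensitivities here are Gaussian stand-ins with the conventional
peak wavelengths; real sensitivity curves can be substituted channel by
channel. Calibrated camera channels are converted to receptor catches by
ordinary least squares over polynomial terms of the camera channels (degree
1 or 2 with pairwise interactions), the standard mapping technique for
multispectral photography.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .calibration import MultispectralImage
from .spectra import check_on_grid, gaussian_band

#: Floor applied to predicted catches so downstream log contrasts are finite.
CATCH_EPSILON = 1e-6


@dataclass
class ReceptorChannel:
    """One receptor class: sensitivity, Weber fraction and relative density.

    ``weber_fraction`` (e) sets the discrimination noise of the channel;
    ``relative_density`` (η) is its relative abundance, used to derive the
    full noise set from a single reference Weber fraction (e_i = ω/√η_i).
    """

    name: str
    weber_fraction: float
    relative_density: float
    sensitivity: np.ndarray | None = None

    def __post_init__(self):
        if self.weber_fraction <= 0:
            raise ValueError("weber_fraction must be positive")
        if self.relative_density <= 0:
            raise ValueError("relative_density must be positive")
        if self.sensitivity is not None:
            self.sensitivity = check_on_grid(self.sensitivity, self.name)


@dataclass
class VisualSystem:
    """Ordered chromatic receptors plus one luminance receptor."""

    name: str
    chromatic_channels: list[ReceptorChannel]
    luminance_channel: ReceptorChannel

    def __post_init__(self):
        if not 2 <= len(self.chromatic_channels) <= 4:
            raise ValueError("need 2-4 chromatic channels")

    @property
    def chromatic_names(self) -> list[str]:
        return [c.name for c in self.chromatic_channels]

    @property
    def receptor_names(self) -> list[str]:
        return self.chromatic_names + [self.luminance_channel.name]

    def sensitivity_matrix(self) -> np.ndarray:
        chans = self.chromatic_channels + [self.luminance_channel]
        missing = [c.name for c in chans if c.sensitivity is None]
        if missing:
            raise ValueError(f"receptors lack sensitivity curves: {missing}")
        return np.stack([c.sensitivity for c in chans])


def _with_webers(channels: list[tuple[str, float, float]],
                 reference_weber: float) -> list[ReceptorChannel]:
    """Derive e_i = ω/√η_i with ω anchored so the most abundant chromatic
    channel gets e = reference_weber."""
    densities = np.array([d for _, _, d in channels])
    omega = reference_weber * np.sqrt(densities.max())
    return [ReceptorChannel(name=n,
                            weber_fraction=float(omega / np.sqrt(d)),
                            relative_density=d,
                            sensitivity=gaussian_band(peak, sigma))
            for (n, peak, d), sigma in zip(channels, _SIGMAS)]


_SIGMAS = (18.0, 25.0, 30.0, 35.0)


def peafowl(reference_weber: float = 0.05) -> VisualSystem:
    """Violet-type tetrachromat bird; relative cone densities
    UV:SW:MW:LW = 1.0:1.9:2.2:2.1, double-cone luminance channel."""
    chans = _with_webers([("UVS", 405.0, 1.0), ("SWS", 445.0, 1.9),
                          ("MWS", 508.0, 2.2), ("LWS", 565.0, 2.1)],
                         reference_weber)
    dbl = ReceptorChannel(name="DBL", weber_fraction=reference_weber,
                          relative_density=1.0,
                          sensitivity=gaussian_band(560.0, 50.0))
    return VisualSystem(name="peafowl", chromatic_channels=chans,
                        luminance_channel=dbl)


def pollack(reference_weber: float = 0.05) -> VisualSystem:
    """Dichromatic fish predator (SW + LW cones, densities 1:2); LW-based
    luminance channel (no double cones in fish)."""
    chans = [ReceptorChannel(name="SWS",
                             weber_fraction=reference_weber * np.sqrt(2.0),
                             relative_density=1.0,
                             sensitivity=gaussian_band(455.0, 30.0)),
             ReceptorChannel(name="LWS", weber_fraction=reference_weber,
                             relative_density=2.0,
                             sensitivity=gaussian_band(530.0, 35.0))]
    lum = ReceptorChannel(name="LUM", weber_fraction=reference_weber,
                          relative_density=1.0,
                          sensitivity=gaussian_band(530.0, 50.0))
    return VisualSystem(name="pollack", chromatic_channels=chans,
                        luminance_channel=lum)


# ---------------------------------------------------------------------------
# polynomial mapping

def polynomial_terms(channel_names: list[str], degree: int) -> list[tuple[str, ...]]:
    """Fixed, documented term list: intercept, linear terms in declared
    channel order, then pairwise products x_i*x_j with i<=j (degree 2)."""
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    terms: list[tuple[str, ...]] = [()]
    terms += [(n,) for n in channel_names]
    if degree == 2:
        for i, a in enumerate(channel_names):
            for b in channel_names[i:]:
                terms.append((a, b))
    return terms


def _design_matrix(responses: np.ndarray, n_channels: int,
                   terms: list[tuple[str, ...]],
                   channel_names: list[str]) -> np.ndarray:
    cols = {n: responses[:, i] for i, n in enumerate(channel_names)}
    X = np.empty((responses.shape[0], len(terms)))
    for j, t in enumerate(terms):
        col = np.ones(responses.shape[0])
        for n in t:
            col = col * cols[n]
        X[:, j] = col
    return X


@dataclass
class ConeMapping:
    """Per-receptor OLS coefficients over polynomial camera-channel terms."""

    channel_names: list[str]
    receptor_names: list[str]
    degree: int
    coefficients: np.ndarray          # (n_terms, n_receptors)
    r_squared: dict[str, float] = field(default_factory=dict)

    @property
    def terms(self) -> list[tuple[str, ...]]:
        return polynomial_terms(self.channel_names, self.degree)

    def to_json(self) -> str:
        return json.dumps({
            "channel_names": self.channel_names,
            "receptor_names": self.receptor_names,
            "degree": self.degree,
            "terms": ["*".join(t) if t else "1" for t in self.terms],
            "coefficients": self.coefficients.tolist(),
            "r_squared": self.r_squared,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ConeMapping":
        d = json.loads(text)
        return cls(channel_names=d["channel_names"],
                   receptor_names=d["receptor_names"], degree=d["degree"],
                   coefficients=np.asarray(d["coefficients"]),
                   r_squared=d["r_squared"])


def fit_cone_mapping(camera_responses: np.ndarray, cone_catches: np.ndarray,
                     channel_names: list[str], receptor_names: list[str],
                     degree: int = 2) -> ConeMapping:
    """Least-squares fit of receptor catches on polynomial camera terms.

    Raises on a rank-deficient design, naming the collinear terms, and on a
    sample too small for the term count. Reports in-sample R² per receptor.
    """
    X_resp = np.asarray(camera_responses, dtype=float)
    Y = np.asarray(cone_catches, dtype=float)
    if not (np.all(np.isfinite(X_resp)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite values in training data")
    terms = polynomial_terms(channel_names, degree)
    if X_resp.shape[0] < len(terms):
        raise ValueError(
            f"need at least {len(terms)} samples for {len(terms)} terms, "
            f"got {X_resp.shape[0]}")
    X = _design_matrix(X_resp, len(channel_names), terms, channel_names)

    # rank check with named culprits via pivoted QR
    from scipy.linalg import qr
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [terms[piv[i]] for i in range(len(terms)) if diag[i] <= tol]
    if bad:
        names = ["*".join(t) if t else "1" for t in bad]
        raise ValueError(f"rank-deficient design; collinear terms: {names}")

    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ coef
    ss_res = ((Y - fitted) ** 2).sum(axis=0)
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    r2 = {n: float(1.0 - ss_res[i] / ss_tot[i]) if ss_tot[i] > 0 else 1.0
          for i, n in enumerate(receptor_names)}
    return ConeMapping(channel_names=list(channel_names),
                       receptor_names=list(receptor_names), degree=degree,
                       coefficients=coef, r_squared=r2)


def apply_cone_mapping(img: MultispectralImage, m: ConeMapping) -> MultispectralImage:
    """Per-pixel polynomial evaluation of the mapping.

    Negative predictions are floored at ``CATCH_EPSILON`` so log contrasts
    downstream stay finite.
    """
    missing = [n for n in m.channel_names if n not in img.channels]
    if missing:
        raise ValueError(f"image lacks camera channels {missing}")
    h, w = img.shape
    flat = np.stack([img.channels[n].ravel() for n in m.channel_names], axis=1)
    X = _design_matrix(flat, len(m.channel_names), m.terms, m.channel_names)
    pred = np.maximum(X @ m.coefficients, CATCH_EPSILON)
    channels = {n: pred[:, i].reshape(h, w)
                for i, n in enumerate(m.receptor_names)}
    return MultispectralImage(channels=channels, px_per_mm=img.px_per_mm,
                              masks=dict(img.masks))


def mean_catches(img: MultispectralImage, roi: np.ndarray) -> dict[str, float]:
    """Arithmetic mean catch per receptor over a region of interest."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    return {n: float(c[roi].mean()) for n, c in img.channels.items()}
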