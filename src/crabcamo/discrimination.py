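"""Receptor-noise-limited colour and luminance discrimination (JNDs).

The log-linear receptor-noise model: receptor contrasts are differences of
log catches, Δf_i = ln(q_A,i) − ln(q_B,i), and chromatic distance weights
the pairwise contrast differences by the channel noise levels e_i:

    ΔS² = Σ_{i<j} (Π_{k∉{i,j}} e_k)² (Δf_i − Δf_j)²
          ─────────────────────────────────────────
                  Σ_i (Π_{k≠i} e_k)²

which reduces to the published closed forms for di-, tri- and
tetrachromats. Achromatic (luminance) distance is |Δf_L| / e_L. A JND
below ~1.0 means the modelled viewer cannot discriminate the two stimuli;
larger values mean progressively poorer camouflage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Conventional discriminability threshold for the RNL model.
JND_THRESHOLD = 1.0


@dataclass
class NoiseModel:
    """Noise levels per chromatic channel plus the luminance channel."""

    e: np.ndarray       # (n_chromatic,) noise of each chromatic channel
    e_lum: float

    def __post_init__(self):
        self.e = np.asarray(self.e, dtype=float)
        if np.any(self.e <= 0) or self.e_lum <= 0:
            raise ValueError("all noise values must be positive")
        if not 2 <= self.e.size <= 4:
            raise ValueError("need 2-4 chromatic channels")

    @classmethod
    def from_visual_system(cls, vs) -> "NoiseModel":
        return cls(e=np.array([c.weber_fraction for c in vs.chromatic_channels]),
                   e_lum=vs.luminance_channel.weber_fraction)


def receptor_contrasts(qA: np.ndarray, qB: np.ndarray) -> np.ndarray:
    """Log receptor contrasts Δf_i = ln(qA_i) − ln(qB_i)."""
    qA = np.asarray(qA, dtype=float)
    qB = np.asarray(qB, dtype=float)
    if qA.shape != qB.shape:
        raise ValueError("stimuli have different channel counts")
    if np.any(qA <= 0) or np.any(qB <= 0):
        raise ValueError("cone catches must be strictly positive")
    return np.log(qA) - np.log(qB)


def chromatic_jnd(qA: np.ndarray, qB: np.ndarray, noise: NoiseModel) -> float:
    """Chromatic distance in JND for an n-channel viewer (n = 2..4).

    Invariant to a common intensity scaling of either stimulus (all Δf
    shift equally, and only pairwise differences enter).
    """
    df = receptor_contrasts(qA, qB)
    e = noise.e
    n = e.size
    if df.size != n:
        raise ValueError(f"expected {n} chromatic catches, got {df.size}")
    # products of all e except one / except a pair, via total product
    num = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            others = np.prod([e[k] for k in range(n) if k not in (i, j)])
            num += others ** 2 * (df[i] - df[j]) ** 2
    den = sum(np.prod([e[k] for k in range(n) if k != i]) ** 2
              for i in range(n))
    return float(np.sqrt(num / den))


def luminance_jnd(qA_lum: float, qB_lum: float, noise: NoiseModel) -> float:
    """Achromatic distance |ln(qA/qB)| / e_L in JND. Symmetric in A and B."""
    if qA_lum <= 0 or qB_lum <= 0:
        raise ValueError("luminance catches must be strictly positive")
    return float(abs(np.log(qA_lum / qB_lum)) / noise.e_lum)


def is_indistinguishable(jnd: float) -> bool:
    """Interpretation contract: JND < 1.0 predicts no discrimination."""
    return jnd < JND_THRESHOLD


def mean_jnd_to_habitat(crab_chromatic: np.ndarray, crab_lum: float,
                        backgrounds: list[tuple[np.ndarray, float]],
                        noise: NoiseModel) -> tuple[float, float]:
    """Average (chromatic, luminance) JND of one crab against a habitat.

    ``backgrounds`` holds one (chromatic catches, luminance catch) stimulus
    per background image; the habitat score is the arithmetic mean of the
    per-image JNDs.
    """
    if not backgrounds:
        raise ValueError("need at least one background stimulus")
    cs = [chromatic_jnd(crab_chromatic, q, noise) for q, _ in backgrounds]
    ls = [luminance_jnd(crab_lum, l, noise) for _, l in backgrounds]
    return float(np.mean(cs)), float(np.mean(ls))
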