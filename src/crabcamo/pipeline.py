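"""End-to-end synthetic study: generate, train, measure, analyse.

Mirrors the field workflow: photograph backgrounds of two habitat classes
and crabs of two origins, calibrate images against the embedded standards,
convert to predator cone catches via the trained polynomial mapping, then
score each crab against every background of each habitat for colour and
luminance JNDs, pattern energy difference and GabRat edge disruption, and
feed the per-crab habitat means into the split-plot ANOVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import calibration, discrimination, disruption, pattern, stats, synthetic, vision
from .spectra import CameraModel

HABITATS = ("MF", "RP")


@dataclass
class PipelineConfig:
    """Study-design knobs with the sampling defaults of the field study
    (47 backgrounds per habitat, 50 placements per background)."""

    seed: int = 0
    n_backgrounds_per_habitat: int = 47
    n_crabs_per_origin: int = 20
    scene_size: tuple[int, int] = (1024, 1024)
    px_per_mm: float = 10.0
    placements: int = 50
    library_size: int = 200
    mapping_degree: int = 2
    reference_weber: float = 0.05
    carapace_range_mm: tuple[float, float] = (6.0, 9.0)
    blotch_count_range: tuple[int, int] = (6, 13)
    blotch_contrast_range: tuple[float, float] = (0.5, 0.9)
    edge_bias: float = 0.8
    gabor: disruption.GaborParams = dc_field(default_factory=disruption.GaborParams)
    pattern_scales: list[float] | None = None

    def __post_init__(self):
        if self.n_backgrounds_per_habitat < 1 or self.n_crabs_per_origin < 1:
            raise ValueError("counts must be >= 1")
        if self.placements < 1:
            raise ValueError("placements must be >= 1")

    def scales(self) -> list[float]:
        if self.pattern_scales is not None:
            return list(self.pattern_scales)
        return pattern.default_scales(min(self.scene_size))


@dataclass
class SyntheticStudy:
    """All generated inputs of one synthetic study."""

    config: PipelineConfig
    camera: CameraModel
    library: np.ndarray
    backgrounds: list[tuple[str, synthetic.Scene]]      # (habitat, scene)
    crabs: list[tuple[str, str, synthetic.CrabPatch]]   # (crab_id, origin, patch)


def _crab_phenotype(origin: str, rng: np.random.Generator,
                    cfg: PipelineConfig) -> synthetic.CrabPhenotype:
    width = rng.uniform(*cfg.carapace_range_mm)
    if origin == "MF":
        # mudflat juveniles: uniform, mud-matched carapace
        base = np.clip(synthetic.mud_spectrum()
                       * math.exp(rng.normal(0.0, 0.08)), 0.01, 0.99)
        return synthetic.CrabPhenotype(style="uniform", base_spectrum=base,
                                       carapace_width=width)
    # rock-pool juveniles: margin-biased high-contrast blotches on a
    # rock/sand mixed base
    mix = rng.uniform(0.3, 0.7)
    base = np.clip((mix * synthetic.sand_spectrum()
                    + (1 - mix) * synthetic.rock_light_spectrum())
                   * math.exp(rng.normal(0.0, 0.10)), 0.01, 0.99)
    return synthetic.CrabPhenotype(
        style="disruptive", base_spectrum=base,
        blotch_count=int(rng.integers(*cfg.blotch_count_range)),
        blotch_contrast=float(rng.uniform(*cfg.blotch_contrast_range)),
        edge_bias=cfg.edge_bias, carapace_width=width)


def generate_study(cfg: PipelineConfig) -> SyntheticStudy:
    """Generate backgrounds, crabs and the mapping-training library."""
    rng = np.random.default_rng(cfg.seed)
    camera = CameraModel.default()
    library = synthetic.make_spectrum_library(cfg.library_size, cfg.seed)

    backgrounds = []
    for habitat, params in (("MF", synthetic.HabitatTextureParams.mudflat()),
                            ("RP", synthetic.HabitatTextureParams.rockpool())):
        for i in range(cfg.n_backgrounds_per_habitat):
            scene_seed = int(rng.integers(0, 2 ** 31))
            backgrounds.append((habitat, synthetic.make_background_scene(
                params, size=cfg.scene_size, seed=scene_seed,
                px_per_mm=cfg.px_per_mm)))

    crabs = []
    for origin in ("MF", "RP"):
        for i in range(cfg.n_crabs_per_origin):
            crab_seed = int(rng.integers(0, 2 ** 31))
            phen = _crab_phenotype(origin, rng, cfg)
            crabs.append((f"{origin}{i:03d}", origin,
                          synthetic.make_crab(phen, cfg.px_per_mm, crab_seed)))
    return SyntheticStudy(config=cfg, camera=camera, library=library,
                          backgrounds=backgrounds, crabs=crabs)


def train_mappings(study: SyntheticStudy) -> dict[str, vision.ConeMapping]:
    """Fit the camera→cone polynomial mapping for both visual systems from
    the spectrum library's rendered camera responses and true catches."""
    cfg = study.config
    cam_resp = synthetic.normalized_catches(
        study.library, study.camera.sensitivity_matrix())
    mappings = {}
    for vs in (vision.peafowl(cfg.reference_weber),
               vision.pollack(cfg.reference_weber)):
        catches = synthetic.normalized_catches(study.library,
                                               vs.sensitivity_matrix())
        mappings[vs.name] = vision.fit_cone_mapping(
            cam_resp, catches, study.camera.channel_names, vs.receptor_names,
            degree=cfg.mapping_degree)
    return mappings


@dataclass
class _PreparedBackground:
    habitat: str
    stimuli: dict[str, tuple[np.ndarray, float]]  # per vs: (chromatic, lum)
    lum: np.ndarray                               # avian double-cone raster
    spectrum: pattern.PatternSpectrum
    exclusion: np.ndarray


def prepare_background(habitat: str, scene: synthetic.Scene,
                       camera: CameraModel,
                       mappings: dict[str, vision.ConeMapping],
                       systems: dict[str, vision.VisualSystem],
                       scales: list[float]) -> _PreparedBackground:
    """Calibrate one background and derive its per-viewer stimuli, luminance
    raster and granularity spectrum."""
    raw = synthetic.render_camera_image(scene, camera)
    std = calibration.measure_standards(raw, scene.masks["standard_black"],
                                        scene.masks["standard_white"])
    refl = calibration.normalize_to_reflectance(raw, std)
    frac = calibration.MultispectralImage(
        channels={n: c / 100.0 for n, c in refl.channels.items()},
        px_per_mm=refl.px_per_mm, masks=refl.masks)
    usable = scene.usable()
    stimuli = {}
    lum = None
    for name, m in mappings.items():
        catches = vision.apply_cone_mapping(frac, m)
        vs = systems[name]
        means = vision.mean_catches(catches, usable)
        stimuli[name] = (np.array([means[c] for c in vs.chromatic_names]),
                         means[vs.luminance_channel.name])
        if name == "peafowl":
            lum = catches.channels[vs.luminance_channel.name]
    spectrum = pattern.granularity_spectrum(lum, usable, scales)
    return _PreparedBackground(habitat=habitat, stimuli=stimuli, lum=lum,
                               spectrum=spectrum,
                               exclusion=scene.placement_exclusion())


def _prepare_crab(crab: synthetic.CrabPatch, camera: CameraModel,
                  mappings, systems, scales, scene_shape):
    raw = synthetic.render_crab_camera_image(crab, camera)
    stimuli = {}
    lum_patch = None
    for name, m in mappings.items():
        catches = vision.apply_cone_mapping(raw, m)
        vs = systems[name]
        means = vision.mean_catches(catches, crab.mask)
        stimuli[name] = (np.array([means[c] for c in vs.chromatic_names]),
                         means[vs.luminance_channel.name])
        if name == "peafowl":
            lum_patch = catches.channels[vs.luminance_channel.name]
    # granularity of the carapace at matched scales: embed the patch in a
    # scene-sized canvas (mean fill happens inside granularity_spectrum)
    canvas = np.full(scene_shape, lum_patch[crab.mask].mean())
    roi = np.zeros(scene_shape, dtype=bool)
    h, w = crab.mask.shape
    oy = (scene_shape[0] - h) // 2
    ox = (scene_shape[1] - w) // 2
    canvas[oy:oy + h, ox:ox + w] = np.where(
        crab.mask, lum_patch, canvas[oy:oy + h, ox:ox + w])
    roi[oy:oy + h, ox:ox + w] = crab.mask
    spectrum = pattern.granularity_spectrum(canvas, roi, scales)
    return stimuli, lum_patch, spectrum


def measure_study(study: SyntheticStudy,
                  mappings: dict[str, vision.ConeMapping] | None = None,
                  progress: bool = False) -> pd.DataFrame:
    """Produce the measurement table: one row per crab × background habitat
    with all six camouflage metrics."""
    cfg = study.config
    mappings = mappings or train_mappings(study)
    systems = {"peafowl": vision.peafowl(cfg.reference_weber),
               "pollack": vision.pollack(cfg.reference_weber)}
    noises = {n: discrimination.NoiseModel.from_visual_system(v)
              for n, v in systems.items()}
    scales = cfg.scales()

    prepared = [prepare_background(h, s, study.camera, mappings, systems, scales)
                for h, s in study.backgrounds]

    rows = []
    for ci, (crab_id, origin, crab) in enumerate(study.crabs):
        stimuli, lum_patch, crab_spec = _prepare_crab(
            crab, study.camera, mappings, systems, scales, cfg.scene_size)
        engine = disruption.GabRatEngine(crab.mask, cfg.gabor)
        per_habitat: dict[str, dict[str, list[float]]] = {
            h: {k: [] for k in stats.METRIC_COLUMNS} for h in HABITATS}
        for bi, bg in enumerate(prepared):
            acc = per_habitat[bg.habitat]
            for vs_name, metric_prefix in (("peafowl", "avian"),
                                           ("pollack", "fish")):
                cq, cl = stimuli[vs_name]
                bq, bl = bg.stimuli[vs_name]
                acc[f"jnd_colour_{metric_prefix}"].append(
                    discrimination.chromatic_jnd(cq, bq, noises[vs_name]))
                acc[f"jnd_lum_{metric_prefix}"].append(
                    discrimination.luminance_jnd(cl, bl, noises[vs_name]))
            acc["ped"].append(pattern.ped(crab_spec, bg.spectrum))
            seed = (cfg.seed * 1000003 + ci * 9973 + bi * 7 + 1) % (2 ** 31)
            mg, _ = disruption.mean_gabrat(
                lum_patch, crab.mask, bg.lum, n=cfg.placements,
                exclusion=bg.exclusion, seed=seed, engine=engine)
            acc["gabrat"].append(mg)
        for h in HABITATS:
            row = {"crab_id": crab_id, "origin": origin, "background": h}
            row.update({k: float(np.mean(v))
                        for k, v in per_habitat[h].items()})
            rows.append(row)
        if progress:
            print(f"measured crab {crab_id} ({ci + 1}/{len(study.crabs)})")
    return pd.DataFrame(rows, columns=stats.FACTOR_COLUMNS + stats.METRIC_COLUMNS)


def gabrat_phenotype_sweep(seed: int = 0, n_backgrounds: int = 2,
                           scene_size: tuple[int, int] = (768, 768),
                           placements: int = 5, px_per_mm: float = 15.0,
                           gabor: disruption.GaborParams | None = None,
                           n_crabs: int = 3) -> pd.DataFrame:
    """Mean GabRat across a ladder of crab phenotypes on both habitats.

    The ladder runs from large uniform background-mismatching crabs (a
    salient coherent outline, minimal edge disruption) to dense thin
    margin-crossing blotch phenotypes (strong disruption). Luminance is the
    avian double-cone channel. Returns one row per crab × background with
    the placement-averaged GabRat.
    """
    rng = np.random.default_rng(seed)
    lum_sens = vision.peafowl().luminance_channel.sensitivity

    def _lum(labels, spectra):
        return synthetic.normalized_catches(
            spectra, lum_sens[None, :])[:, 0][labels]

    ladder = []
    for width in (10.0, 12.0, 14.0):
        ladder.append((f"uniform_w{width:g}", synthetic.CrabPhenotype(
            style="uniform", base_spectrum=synthetic.sand_spectrum(),
            carapace_width=width)))
    for nb, c, width in ((6, 0.3, 10.0), (12, 0.6, 8.0), (24, 0.9, 8.0)):
        ladder.append((f"disruptive_n{nb}_c{c:g}", synthetic.CrabPhenotype(
            style="disruptive",
            base_spectrum=synthetic.rock_light_spectrum(),
            blotch_count=nb, blotch_contrast=c, edge_bias=0.9,
            carapace_width=width)))

    scenes = []
    for habitat, params in (("MF", synthetic.HabitatTextureParams.mudflat()),
                            ("RP", synthetic.HabitatTextureParams.rockpool())):
        for _ in range(n_backgrounds):
            s = synthetic.make_background_scene(
                params, size=scene_size, seed=int(rng.integers(0, 2 ** 31)),
                px_per_mm=px_per_mm)
            scenes.append((habitat, _lum(s.labels, s.spectra),
                           s.placement_exclusion()))

    rows = []
    for name, phen in ladder:
        for k in range(n_crabs):
            crab = synthetic.make_crab(phen, px_per_mm,
                                       int(rng.integers(0, 2 ** 31)))
            lum = _lum(crab.labels, crab.spectra)
            engine = disruption.GabRatEngine(crab.mask, gabor)
            for bi, (habitat, bg_lum, excl) in enumerate(scenes):
                m, _ = disruption.mean_gabrat(
                    lum, crab.mask, bg_lum, n=placements, exclusion=excl,
                    seed=int(rng.integers(0, 2 ** 31)), engine=engine)
                rows.append({"phenotype": name, "style": phen.style,
                             "crab": k, "habitat": habitat,
                             "background": bi, "gabrat": m})
    return pd.DataFrame(rows)


def run_all(cfg: PipelineConfig, progress: bool = False) -> dict:
    """Generate → train → measure → analyse; returns the full report."""
    study = generate_study(cfg)
    mappings = train_mappings(study)
    table = measure_study(study, mappings, progress=progress)
    report = stats.run_full_analysis(table)
    report["measurements"] = table
    report["mappings"] = mappings
    return report
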