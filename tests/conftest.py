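import pytest

import crabcamo as cc
from crabcamo import synthetic, vision


@pytest.fixture(scope="session")
def camera():
    return cc.CameraModel.default()


@pytest.fixture(scope="session")
def peafowl_vs():
    return vision.peafowl()


@pytest.fixture(scope="session")
def pollack_vs():
    return vision.pollack()


@pytest.fixture(scope="session")
def mudflat_scene():
    return cc.make_background_scene(cc.HabitatTextureParams.mudflat(),
                                    size=(320, 320), seed=11)


@pytest.fixture(scope="session")
def rockpool_scene():
    return cc.make_background_scene(cc.HabitatTextureParams.rockpool(),
                                    size=(320, 320), seed=11)


@pytest.fixture(scope="session")
def luminance_sensitivity(peafowl_vs):
    return peafowl_vs.luminance_channel.sensitivity


def scene_luminance(scene, lum_sens):
    """Ground-truth double-cone luminance raster of a palette scene."""
    catches = synthetic.normalized_catches(scene.spectra, lum_sens[None, :])
    return catches[:, 0][scene.labels]


@pytest.fixture(scope="session")
def mudflat_luminance(mudflat_scene, luminance_sensitivity):
    return scene_luminance(mudflat_scene, luminance_sensitivity)


@pytest.fixture(scope="session")
def rockpool_luminance(rockpool_scene, luminance_sensitivity):
    return scene_luminance(rockpool_scene, luminance_sensitivity)


@pytest.fixture(scope="session")
def uniform_crab():
    phen = cc.CrabPhenotype(style="uniform",
                            base_spectrum=synthetic.sand_spectrum(),
                            carapace_width=6.0)
    return cc.make_crab(phen, px_per_mm=10.0, seed=7)


@pytest.fixture(scope="session")
def disruptive_crab():
    phen = cc.CrabPhenotype(style="disruptive",
                            base_spectrum=synthetic.rock_light_spectrum(),
                            blotch_count=12, blotch_contrast=0.8,
                            edge_bias=0.8, carapace_width=6.0)
    return cc.make_crab(phen, px_per_mm=10.0, seed=7)


def crab_luminance(crab, lum_sens):
    catches = synthetic.normalized_catches(crab.spectra, lum_sens[None, :])
    return catches[:, 0][crab.labels]
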