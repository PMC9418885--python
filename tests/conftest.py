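import dataclasses

import numpy as np
import pytest

from ommech import synthgen
from ommech.synthgen.presets import SceneSpec


@pytest.fixture(scope="session")
def dmpc20_preset():
    return synthgen.get_force_preset("DMPC-20C")


@pytest.fixture(scope="session")
def lps_dmpc_preset():
    return synthgen.get_force_preset("LPS-DMPC")


def small_scene(name: str, px: int = 256, **overrides) -> SceneSpec:
    """A shrunken copy of a built-in scene preset for fast tests."""
    scene = dataclasses.replace(synthgen.get_scene_preset(name),
                                pixels_per_side=px, **overrides)
    scene.validate()
    return scene


@pytest.fixture(scope="session")
def flat_two_phase_scene():
    """512x512 gel/fluid DMPC scene used by several segmentation tests."""
    scene = small_scene("DMPC-20C", px=512)
    return synthgen.gen_height_map(scene, seed=7)


def make_ramp_curve(contact=20.0, stiffness=1.0, start=40.0, stop=-5.0,
                    ds=0.05, noise_sd=0.0, rng=None):
    """Hand-built noiseless (or noisy) linear-loading approach curve."""
    from ommech.datatypes import ForceCurve

    s = np.arange(start, stop, -ds)
    f = np.where(s < contact, stiffness * (contact - s), 0.0)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        f = f + rng.normal(0, noise_sd, len(s))
    return ForceCurve(separation=s, force=f, direction="approach",
                      metadata={"sample": "ramp"})
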