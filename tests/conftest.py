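import pytest

import phenotrack as pt


@pytest.fixture(scope="session")
def noiseless_scene():
    """Clean 120-frame scene with one haploid and one amoeboid cell —
    shared fixture for detection, linking and localization checks."""
    scene = pt.SceneConfig(width=512, height=512, n_frames=120, noise_sd=0.0, seed=7)
    gt, stack = pt.simulate_scene([pt.HAPLOID_PRESET, pt.AMOEBOID_PRESET], scene)
    return scene, gt, stack


@pytest.fixture(scope="session")
def cleaned_scene(noiseless_scene):
    scene, gt, stack = noiseless_scene
    return scene, gt, pt.remove_background(stack)
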