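import numpy as np
import pytest

import bbbhotspots as b


@pytest.fixture(scope="session")
def lesion_phantom():
    """48^3 phantom with lacunes, WMH blobs and microbleeds."""
    spec = b.LesionSpec(
        lacunes=b.LesionClassSpec(3, (2.0, 2.0)),
        wmh_blobs=b.LesionClassSpec(3, (3.0, 4.0)),
        cmbs=b.LesionClassSpec(2, (1.0, 2.0)),
    )
    return b.generate_phantom((48, 48, 48), lesion_spec=spec, seed=11)


@pytest.fixture(scope="session")
def vif():
    return b.generate_vif()


@pytest.fixture(scope="session")
def truth_maps(lesion_phantom):
    spec = (
        b.FocusSpec(3, attach="lacune_rim"),
        b.FocusSpec(6, attach="random_wm"),
        b.FocusSpec(2, attach="within_wmh"),
    )
    return b.generate_truth_maps(lesion_phantom, focus_spec=spec, seed=12)


@pytest.fixture(scope="session")
def analysis_masks(lesion_phantom):
    return b.build_analysis_masks(lesion_phantom.labels)


@pytest.fixture(scope="session")
def noisy_maps(lesion_phantom, truth_maps, vif, analysis_masks):
    dce = b.synthesize_dce(truth_maps, vif, noise_sd=0.01, seed=13)
    return b.map_patlak(dce, vif, analysis_masks.wm_eroded)
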