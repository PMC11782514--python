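"""Shared synthetic scenes, generated once per session.

All fixtures are deterministic (fixed seeds); the heavier scenes are
session-scoped so the planted-truth recovery tests and the end-to-end
tests share one rendering.
"""

import pytest

from colonoidquant import fluo, synthetic

FLUO_MIX = {
    "KI67+CK20+": 0.30,
    "KI67+CK20-": 0.20,
    "KI67-CK20+": 0.20,
    "KI67-CK20-": 0.20,
    "TUNEL+": 0.10,
}


@pytest.fixture(scope="session")
def brightfield_scene():
    return synthetic.generate_brightfield_well(80, seed=3)


@pytest.fixture(scope="session")
def ihc_scene():
    return synthetic.generate_ihc_section(200, 0.4, seed=5)


@pytest.fixture(scope="session")
def fluo_scene():
    return synthetic.generate_fluorescence_section(300, FLUO_MIX, seed=7)


@pytest.fixture(scope="session")
def fluo_cells(fluo_scene):
    image, _ = fluo_scene
    params = fluo.FluoDetectionParams(dapi_min_mean=25.0)
    return fluo.detect_nuclei_fluor(image, params)
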