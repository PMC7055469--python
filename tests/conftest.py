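import warnings

import pytest

from podquant import synth
from podquant.synth import PlacementWarning


@pytest.fixture(scope="session")
def default_scene():
    """One default scene (12 pods, 1 overlap pair) shared across tests."""
    return synth.generate_scene(synth.SceneSpec(seed=7))


@pytest.fixture(scope="session")
def plain_scene():
    """A scene without overlap pairs."""
    with warnings.catch_warnings():
        warnings.simplefilter("error", PlacementWarning)
        return synth.generate_scene(
            synth.SceneSpec(seed=11, n_siliques=10, n_overlap_pairs=0))
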