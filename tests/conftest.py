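import numpy as np
import pytest

import retinoconn as rc


@pytest.fixture(scope="session")
def default_patch():
    return rc.make_retino_patch()


@pytest.fixture(scope="session")
def default_labels(default_patch):
    return rc.make_label_volume(default_patch)


@pytest.fixture()
def gen_cfg():
    return rc.GeneratorConfig(seed=0, n_streamlines=300)


@pytest.fixture(scope="session")
def default_tractogram(default_labels):
    cfg = rc.GeneratorConfig(seed=11, n_streamlines=600)
    return rc.simulate_streamlines(default_labels, cfg)
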