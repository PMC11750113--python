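import numpy as np
import pytest

from uristrip.registration import detect_features
from uristrip.synth import demo_layout, render_template


@pytest.fixture(scope="session")
def layout():
    return demo_layout()


@pytest.fixture(scope="session")
def template(layout):
    return render_template(layout)


@pytest.fixture(scope="session")
def template_features(template):
    return detect_features(template)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
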