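import numpy as np
import pytest

from gapatlas import DomainSpec, make_embryo_image, make_profile
from gapatlas.profiles import EmbryoImage
from gapatlas.synthetic import default_wildtype_dynamics


@pytest.fixture(scope="session")
def kr_domain():
    return DomainSpec("Kr", "central", 40.0, 63.0)


@pytest.fixture(scope="session")
def kr_profile(kr_domain):
    prof, truth = make_profile([kr_domain])
    return prof


@pytest.fixture(scope="session")
def kr_image(kr_profile):
    emb = make_embryo_image(kr_profile, seed=1)
    return EmbryoImage(pixels=emb.image, mask=emb.mask, gene="Kr",
                       embryo_id="kr_c12", time_class="C12")


@pytest.fixture(scope="session")
def wildtype_dynamics():
    return default_wildtype_dynamics()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
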