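import numpy as np
import pytest

from ervclock.simulate import default_template


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def template_type2():
    return default_template(subtype="II")


@pytest.fixture(scope="session")
def cpg_rich_template():
    return default_template(cpg_rich=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(20259)
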