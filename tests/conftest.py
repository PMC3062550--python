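import numpy as np
import pytest

from its_profiler import delimit, synth


@pytest.fixture(scope="session")
def template_set():
    return synth.generate_templates(synth.SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def reference():
    return delimit.default_reference()


@pytest.fixture(scope="session")
def its2_design():
    return synth.design_its2()


@pytest.fixture(scope="session")
def r58s_design():
    return synth.design_58s(np.random.default_rng(4))


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))
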