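import pytest

from ecostoich import synthetic as syn
from ecostoich import multivariate as mv
from ecostoich.microbial_params import params_frame
from ecostoich.soil_chemistry import derive_frame


@pytest.fixture(scope="session")
def cv0_bundle():
    """Noise-free dataset: every replicate equals its group mean."""
    return syn.generate(syn.default_design().with_cv(0.0), seed=0)


@pytest.fixture(scope="session")
def default_bundle():
    """One draw from the default noisy design."""
    return syn.generate(syn.default_design(), seed=0)


@pytest.fixture(scope="session")
def default_features(default_bundle):
    """Assembled 15 x 25 standardized feature matrix."""
    chem = derive_frame(default_bundle.chemistry)
    micro = params_frame(default_bundle.biomass, default_bundle.respiration, chem)
    return mv.assemble_features(default_bundle.enzymes, chem, micro)
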