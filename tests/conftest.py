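from dataclasses import replace

import pytest

from retinerg import ergsim


@pytest.fixture(scope="session")
def clean_acc():
    """No noise, no acquisition filter: compositions are exact sums."""
    return replace(ergsim.DEFAULT_ACCESSORY, noise_sd=0.0, acquisition_band=None)


@pytest.fixture(scope="session")
def noiseless_family(clean_acc):
    """Full default-protocol family, noiseless and unfiltered (shared: the
    decomposition tests only read it)."""
    return ergsim.generate_family(ergsim.default_protocol(), acc=clean_acc,
                                  seed=0)


#: Ground truth planted by the default generator parameter sets.
TRUTH = {
    "rod_rmp3": 450.0, "rod_s": 900.0, "rod_td": 0.0035,
    "rod_vmax": 600.0, "rod_k": 0.05,
    "cone_rmp3": 120.0, "cone_s": 600.0, "cone_td": 0.003,
    "cone_vmax": 150.0, "cone_k": 25.0,
    "pstr": 12.0,
}


@pytest.fixture(scope="session")
def truth():
    return dict(TRUTH)
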