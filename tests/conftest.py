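from dataclasses import replace

import pytest

import larvadisp as ld


@pytest.fixture(scope="session")
def params():
    return ld.ModelParams()


@pytest.fixture(scope="session")
def weights():
    return ld.ScoreWeights()


@pytest.fixture(scope="session")
def default_policies(params, weights):
    """Solved optimal policies (and values) at default grids, per scheme."""
    out = {}
    for scheme in ("nearshore", "diurnal"):
        p = replace(params, predation_scheme=scheme)
        policy, value = ld.solve(p, weights)
        out[scheme] = (p, policy, value)
    return out
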