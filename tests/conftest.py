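import time

import pytest

from hepapop import SCENARIOS, build_default_parameters, run_scenario


@pytest.fixture(scope="session")
def params():
    return build_default_parameters()


@pytest.fixture(scope="session")
def battery(params):
    """All nine scenarios, run once per session: {name: (trajectory, report)}."""
    t0 = time.perf_counter()
    out = {name: run_scenario(name, params) for name in SCENARIOS}
    out["_elapsed_s"] = time.perf_counter() - t0
    return out
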