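import pytest

from capstress.geometry import MorphologyParams, build_half_model
from capstress.scenarios import default_scenarios, run_scenario


@pytest.fixture(scope="session")
def default_mesh():
    return build_half_model(MorphologyParams())


@pytest.fixture(scope="session")
def roster_results():
    """All eight scenarios solved once, keyed by name (control first)."""
    results = {}
    control_pcs = None
    for s in default_scenarios():
        res = run_scenario(s, control_pcs=control_pcs)
        if s.name == "control":
            control_pcs = res.pcs.pcs
        results[s.name] = res
    return results
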