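import pytest

from pestdyn import CANONICAL_ORDER, build_scenario, simulate


@pytest.fixture(scope="session")
def single_trajectories():
    """Default single-species runs, keyed by species id."""
    return {sid: simulate(build_scenario({sid})) for sid in CANONICAL_ORDER}


@pytest.fixture(scope="session")
def pair_trajectory_cp_bf():
    return simulate(build_scenario({"Cp", "Bf"}))
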