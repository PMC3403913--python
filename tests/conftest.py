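import numpy as np
import pytest

from apcva import (
    NetworkVariant,
    build_network,
    preset,
    run_scenario,
)


@pytest.fixture(scope="session")
def default_network():
    """Final published rate set: current Arg306 constant, R18 enabled."""
    return build_network()


@pytest.fixture(scope="session")
def hockin_network():
    return build_network(NetworkVariant(arg306_rate="hockin"))


@pytest.fixture(scope="session")
def fig3_hockin_result():
    """20 nM FVa + 0.5 nM APC, original bovine-derived Arg306 rate, 20 min."""
    return run_scenario(
        preset("fig3_fva_only", variant=NetworkVariant(arg306_rate="hockin"))
    )


@pytest.fixture(scope="session")
def fig3_current_result():
    """20 nM FVa + 0.5 nM APC, human-adjusted Arg306 rate, 20 min."""
    return run_scenario(preset("fig3_fva_only"))


@pytest.fixture(scope="session")
def fig9_result():
    """FVa + FXa* + PT ternary pre-incubation, 2 nM APC at 11 % effective."""
    return run_scenario(preset("fig9_pt_fxa"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120520)
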