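import numpy as np
import pandas as pd
import pytest

from dhcnet import SimulationConfig, VariableTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return SimulationConfig(n_nodes=6, n_samples=30, edge_density=0.25, seed=7)


def make_table(
    continuous: dict[str, np.ndarray],
    discrete: dict[str, np.ndarray] | None = None,
    roles: dict[str, str] | None = None,
) -> VariableTable:
    """Assemble a VariableTable from plain arrays (shared test helper)."""
    cont = pd.DataFrame(continuous)
    cont.index = [f"s{i:03d}" for i in range(len(cont))]
    disc = None
    if discrete:
        disc = pd.DataFrame(discrete, index=cont.index, dtype=int)
    return VariableTable(cont, disc, roles=roles or {})
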