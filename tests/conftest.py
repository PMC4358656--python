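import numpy as np
import pytest

from bcelldyn.engine import default_config, run_population
from bcelldyn.fixtures import FixtureParams, generate_lineages


@pytest.fixture(scope="session")
def fixture_tree_2000():
    """Synthetic lineage forest with known ground truth (2,000 founders)."""
    params = FixtureParams()
    tree, truth = generate_lineages(params, 2000, seed=7)
    return params, tree, truth


@pytest.fixture(scope="session")
def small_run():
    """Tiny calibrated simulation for structural checks."""
    cfg = default_config(n_agents=12, seed=3)
    tree, manifest = run_population(cfg)
    return cfg, tree, manifest


@pytest.fixture(scope="session")
def wt_run_250():
    """The wild-type study condition: 250 agents, 144 h, fixed seed."""
    cfg = default_config(n_agents=250, seed=1)
    tree, manifest = run_population(cfg)
    return cfg, tree, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
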