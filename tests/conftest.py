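import pytest

from bacmap.simulate import SimConfig
from bacmap.workflow import run_experiment


@pytest.fixture(scope="session")
def default_result():
    """One full experiment under the default study conditions."""
    return run_experiment(SimConfig(seed=1))


@pytest.fixture(scope="session")
def clean_result():
    """No chimeras, no rearrangements, no inflation: every fully placed
    clone should classify as consistent (up to distance-bound tails)."""
    from bacmap.pairs import ConsistencyPolicy

    cfg = SimConfig(seed=11, inflation_factor=1.0,
                    n_rearrangements_per_chromosome=0, chimera_rate=0.0,
                    n_clones=2500)
    policy = ConsistencyPolicy(cfg.insert_mean - 4 * cfg.insert_sd,
                               cfg.insert_mean + 4 * cfg.insert_sd)
    return run_experiment(cfg, policy=policy, crosscheck=False)
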