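import pytest

import lineage_rates as lr
from lineage_rates import simulate as sim


@pytest.fixture(scope="session")
def tree():
    return lr.default_tree()


@pytest.fixture(scope="session")
def timing():
    return lr.default_timing()


@pytest.fixture(scope="session")
def recovery_sim(tree):
    """Noiseless expected-mode simulation of the standard 100-gene cohort."""
    zyg, designed, onset = sim.rate_recovery_cohort(seed=11)
    specs = sim.maternal_background(seed=12) + zyg
    truth = sim.simulate_lineage(tree, specs, seed=13, partition_mode="expected")
    return truth, designed, onset


@pytest.fixture(scope="session")
def noisy_sim(tree):
    """Binomial-partitioned simulation of the same cohort, depth-1e6 render."""
    zyg, designed, onset = sim.rate_recovery_cohort(seed=11)
    specs = sim.maternal_background(seed=12) + zyg
    truth = sim.simulate_lineage(tree, specs, seed=13, partition_mode="binomial")
    expr = sim.render_scrnaseq(truth, depth=1_000_000, seed=14)
    return truth, expr, designed, onset
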