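import numpy as np
import pytest

from leafgwas import simulate as sim
from leafgwas.leafgen import LeafShapeParams, render_leaf


@pytest.fixture(scope="session")
def small_cross():
    """100 clones x 120 SNPs on 3 chromosomes, 5% missing."""
    cfg = sim.CrossConfig(
        n_clones=100, n_chromosomes=3, snps_per_chromosome=40,
        missing_rate=0.05, seed=2,
    )
    return sim.simulate_cross(cfg)


@pytest.fixture(scope="session")
def small_trial_phenotypes():
    """Balanced 2-trait RCBD: 40 clones, 3 blocks, 4 cuttings."""
    trial = sim.TrialConfig(
        V_G=np.array([[1.0, 0.3], [0.3, 0.8]]),
        V_E=np.array([[1.0, 0.2], [0.2, 1.5]]),
        n_blocks=3, cuttings_per_plot=4, survival_rate=1.0, seed=7,
    )
    return sim.simulate_rcbd_phenotypes(trial, n_clones=40)


@pytest.fixture(scope="session")
def ellipse_leaf():
    return render_leaf(LeafShapeParams(family="ellipse", a=60.0, b=40.0))


@pytest.fixture(scope="session")
def circle_leaf():
    return render_leaf(LeafShapeParams(family="circle", a=50.0, b=50.0))
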