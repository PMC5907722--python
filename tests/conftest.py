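import numpy as np
import pytest

from omicsfuse import OmicsLayer, SimulationDesign, simulate_multiomics


def make_layer(name, n, p, seed=0, values=None):
    rng = np.random.RandomState(seed)
    if values is None:
        values = rng.randn(n, p)
    return OmicsLayer(
        name,
        [f"s{i}" for i in range(n)],
        [f"{name}:f{j}" for j in range(p)],
        values,
    )


@pytest.fixture(scope="session")
def small_bundle():
    """Small planted-signal bundle shared across pipeline tests."""
    design = SimulationDesign(
        n_samples=60,
        n_features=(80, 80),
        n_informative=(8, 8),
        overlap_informative=4,
        effect_size=2.5,
        seed=42,
    )
    return simulate_multiomics(design)


@pytest.fixture(scope="session")
def recovery_bundle():
    """Planted-signal fixture: 100 samples, 200 features/layer, 10 planted
    with a 2-sd class shift.

    The planted features carry independent noise (no block correlation):
    with redundant planted features a smaller subset is genuinely optimal
    and the protocol's compactness preference would rightly select it,
    which is not what a recovery fixture should measure.
    """
    design = SimulationDesign(
        n_samples=100,
        n_features=(200, 200),
        n_informative=(10, 10),
        overlap_informative=5,
        effect_size=2.0,
        block_correlation=0.0,
        seed=1234,
    )
    return simulate_multiomics(design)
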