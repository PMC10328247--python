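import numpy as np
import pytest

from micfuzzy import ExpressionDataset, generate_network, simulate_expression


@pytest.fixture
def tiny_ds() -> ExpressionDataset:
    """Two genes, one series of five timepoints, already normalized."""
    mat = np.array(
        [[0.0, 1.0], [0.5, 0.5], [1.0, 0.0], [0.25, 0.75], [0.75, 0.25]]
    )
    return ExpressionDataset(
        gene_ids=["G1", "G2"],
        series=[mat],
        time_stamps=[np.arange(5.0)],
        normalized=True,
    )


@pytest.fixture(scope="session")
def dream_shaped():
    """A DREAM4-shaped instance: 10 genes, 5 series, 21 timepoints."""
    net = generate_network(10, density=2, seed=42)
    ds = simulate_expression(net, timepoints=21, series=5, noise_sd=0.02, seed=42)
    return net, ds
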