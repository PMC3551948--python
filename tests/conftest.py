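import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import adnorm as ad

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_matrix():
    """3 genes x 2 replicates (1 IP, 1 Mock), all finite."""
    values = pd.DataFrame(
        {"ip1": [0.5, 1.25, -0.75], "mock1": [0.0, 0.25, -0.5]},
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )
    return ad.EnrichmentMatrix(
        values=values, conditions=pd.Series({"ip1": "IP", "mock1": "Mock"})
    )


@pytest.fixture
def small_experiment():
    """3v3 simulated experiment small enough for fast unit tests."""
    spec = ad.SimulationSpec(n_genes=1200, target_fraction=0.1, seed=11)
    return ad.simulate_ip_experiment(spec)


def enrichment_per_gene(matrix: ad.EnrichmentMatrix) -> pd.Series:
    """Mean IP minus mean Mock per gene — the quantity the t-test sees."""
    return matrix.values[matrix.ip_ids].mean(axis=1) - matrix.values[
        matrix.mock_ids
    ].mean(axis=1)
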