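import numpy as np
import pandas as pd
import pytest

from covleak import (
    DisclosurePolicy,
    Federation,
    FederationSpec,
    NoisePolicy,
    ServerDataset,
    generate_federation,
)


@pytest.fixture
def open_policy():
    """Disclosure checks switched off (every query passes)."""
    return DisclosurePolicy(enabled=False)


@pytest.fixture
def make_server():
    """Factory for a single-column server from a raw vector."""

    def _make(values, name="x", server_id="s1"):
        return ServerDataset(server_id, pd.DataFrame({name: np.asarray(values, float)}))

    return _make


@pytest.fixture
def make_federation(make_server):
    """Factory for a one-server federation from raw vectors."""

    def _make(columns: dict, policy=None, noise=None, server_id="s1"):
        data = pd.DataFrame({k: np.asarray(v, float) for k, v in columns.items()})
        return Federation(
            [ServerDataset(server_id, data)],
            policy=policy or DisclosurePolicy(enabled=False),
            noise=noise or NoisePolicy(),
        )

    return _make


@pytest.fixture
def bmi_federation():
    """Factory: synthetic single-server federation with a BMI-like column."""

    def _make(n=250, seed=0, policy=None):
        servers, truth = generate_federation(
            FederationSpec(n_per_server=(n,), seed=seed)
        )
        fed = Federation(servers, policy=policy or DisclosurePolicy())
        return fed, truth["server1"]

    return _make


def textbook_cov(x, y):
    """Independent oracle: direct sum-based sample covariance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xbar = sum(x) / n
    ybar = sum(y) / n
    return sum((x[i] - xbar) * (y[i] - ybar) for i in range(n)) / (n - 1)
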