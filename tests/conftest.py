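import numpy as np
import pytest

from fraxkit.hazards import CountryModel, example_risk_config
from fraxkit.io import load_demo_registry
from fraxkit.synthetic import (
    default_true_incidence,
    generate_mortality,
    generate_reference_model,
)


@pytest.fixture(scope="session")
def death_table():
    return generate_mortality(alpha={"female": 1.6e-5, "male": 3.5e-5}, beta=0.095)


@pytest.fixture(scope="session")
def base_model(death_table):
    """Synthetic country model: fitted-style hip hazard, Gompertz mortality,
    example risk-factor table."""
    return CountryModel(
        hip=default_true_incidence(), death=death_table, risk=example_risk_config()
    )


@pytest.fixture(scope="session")
def scaled_model(base_model):
    """Contrast model with hip hazard scaled down to 40% at every age."""
    return generate_reference_model(base_model, 0.4)


@pytest.fixture()
def demo_records():
    return load_demo_registry()


@pytest.fixture(scope="session")
def rank_order_identical():
    """Check that every strictly ordered pair under x is ordered the same
    way under y; exact ties in x are rank-ambiguous and skipped."""

    def check(x, y, rel_tol=1e-9):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        dx = x[:, None] - x[None, :]
        dy = y[:, None] - y[None, :]
        scale = np.maximum(np.abs(x[:, None]), np.abs(x[None, :])) + 1e-300
        strict = np.abs(dx) > rel_tol * scale
        return bool(np.all(np.sign(dx[strict]) == np.sign(dy[strict])))

    return check
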