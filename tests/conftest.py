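import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def simulate_effect_table(
    rng: np.random.Generator,
    mu: float,
    s2_strain: float,
    s2_location: float,
    s2_unit: float,
    k: int = 16,
    n_strains: int = 9,
    n_locations: int = 11,
    vbar: float = 0.003,
) -> pd.DataFrame:
    """Effect sizes from the multilevel model with known components.

    Emulates one trait measured in k populations drawn from a strain x
    institution grid; sampling variances scatter around ``vbar`` (the
    order of magnitude of lnCVR variances at n ~ 400 per sex).
    """
    strains = rng.integers(0, n_strains, k)
    locs = rng.integers(0, n_locations, k)
    u_s = rng.normal(0.0, np.sqrt(s2_strain), n_strains)
    u_l = rng.normal(0.0, np.sqrt(s2_location), n_locations)
    v = vbar * rng.uniform(0.5, 1.5, k)
    y = (
        mu + u_s[strains] + u_l[locs]
        + rng.normal(0.0, np.sqrt(s2_unit), k)
        + rng.normal(0.0, np.sqrt(v))
    )
    return pd.DataFrame(
        {"estimate": y, "sampling_variance": v, "strain": strains, "institution": locs}
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully featured synthetic dataset (records, map, truth)."""
    from dimorph.synthdata import SimulationConfig, generate_dataset

    cfg = SimulationConfig(
        n_traits=10, n_mean=40, n_sd=15, seed=11, true_lnrr=0.1, true_lncvr=0.05
    )
    return generate_dataset(cfg)
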