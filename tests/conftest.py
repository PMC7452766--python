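import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import rafspec

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_design() -> rafspec.DesignConfig:
    return rafspec.DesignConfig(n_locations=8, individuals_per_host=2)


@pytest.fixture(scope="session")
def uniform_dataset(small_design):
    """Small scenario-uniform community with ground truth."""
    return rafspec.simulate_scenario(
        "uniform", n_otus=16, seed=11, design=small_design
    )


@pytest.fixture(scope="session")
def none_dataset(small_design):
    return rafspec.simulate_scenario(
        "none", n_otus=16, seed=11, design=small_design
    )


@pytest.fixture(scope="session")
def quick_mcmc() -> rafspec.McmcConfig:
    return rafspec.McmcConfig(
        n_chains=2, n_warmup=200, n_samples=150, thin=1, n_factors=2, seed=5
    )


@pytest.fixture(scope="session")
def uniform_m2_fit(uniform_dataset, quick_mcmc):
    ds, _ = uniform_dataset
    return rafspec.fit_hurdle(ds, rafspec.ModelSpec.from_name("m2"), quick_mcmc)


def toy_sample_frame(n_locations=3, hosts=("A", "B"), individuals=2,
                     seed=0) -> pd.DataFrame:
    """Minimal valid metadata frame for unit tests."""
    rng = np.random.default_rng(seed)
    rows = []
    elevations = np.linspace(50, 400, n_locations)
    for li in range(n_locations):
        for h in hosts:
            for i in range(individuals):
                rows.append({
                    "sample_id": f"L{li}_{h}_{i}",
                    "location_id": f"L{li}",
                    "host_species": h,
                    "individual_id": f"L{li}_{h}_{i}",
                    "elevation": elevations[li],
                    "soil_ph": 6.0 + rng.normal(0, 0.2),
                    "soil_water": 30.0 + rng.normal(0, 3),
                    "active_layer_depth": 60.0 + rng.normal(0, 5),
                    "vegetation_cover": 70.0 + rng.normal(0, 5),
                    "seq_depth": int(rng.integers(500, 5000)),
                })
    frame = pd.DataFrame(rows)
    return rafspec.community.validate_sample_frame(frame)
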