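import numpy as np
import pandas as pd
import pytest

from coralscale import synthdata as sd
from coralscale import scaling as sc


@pytest.fixture(scope="session")
def default_truth() -> sd.TruthParams:
    """Realistic calcification-like truth used across recovery tests."""
    return sd.TruthParams(ln_alpha=-6.126, beta=0.881, sigma=0.3,
                          sigma_zeta=(0.6, 0.075), rho=-0.58, seed=42)


@pytest.fixture(scope="session")
def colony_table(default_truth) -> pd.DataFrame:
    """One-rate colony table (6 species x 42 colonies) with ground truth."""
    df = sd.gen_colonies(default_truth, n_per_species=42, seed=42, rate_name="rate")
    return df.rename(columns={"surface_area_3d_cm2": "area_cm2"})


@pytest.fixture(scope="session")
def fitted_draws(colony_table) -> sc.PosteriorDraws:
    """A single converged reduced-profile fit, shared by posterior tests."""
    data = sc.ModelData.from_frame(colony_table, "true_rate")
    return sc.sample_posterior(data, cfg=sc.FitConfig(draws_per_chain=1000, warmup=500, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
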