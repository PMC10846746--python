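import numpy as np
import pytest

from renalrec.cohort import generate_cohort, toy_config
from renalrec.model import ModelSpec, SamplerConfig, fit

#: reduced sampler settings shared by the fit-dependent tests
FAST_SAMPLER = dict(max_treedepth=6, target_accept=0.7)


@pytest.fixture(scope="session")
def toy_cohort():
    cfg = toy_config(K=9, L=3, sizes=(4, 3, 2), n_obs=3, p=3, M=3, seed=5,
                     beta_seed=17)
    data, truth = generate_cohort(cfg)
    return cfg, data, truth


@pytest.fixture(scope="session")
def fitted(toy_cohort):
    """One shared two-level fit on the toy cohort."""
    _, data, _ = toy_cohort
    post = fit(data, ModelSpec(),
               SamplerConfig(chains=2, draws=300, warmup=220, seed=42,
                             **FAST_SAMPLER))
    return data, post


@pytest.fixture(scope="session")
def fitted_masked():
    """Fit on a cohort with some albumin cells masked, for imputation tests."""
    cfg = toy_config(K=9, L=3, sizes=(4, 3, 2), n_obs=3, p=3, M=3, seed=11,
                     beta_seed=23)
    data, truth = generate_cohort(cfg)
    alb = data.response_names[-1]
    held = {}
    for row in (1, 7, 13):
        held[row] = float(data.df.loc[row, alb])
        data.df.loc[row, alb] = np.nan
        data.df.loc[row, f"{alb}_status"] = "missing"
    post = fit(data, ModelSpec(),
               SamplerConfig(chains=1, draws=300, warmup=220, seed=7,
                             **FAST_SAMPLER))
    return data, post, truth, held
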