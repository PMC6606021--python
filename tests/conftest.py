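import numpy as np
import pandas as pd
import pytest

from voxsem.growth import GrowthSpec, TwoPartData, TwoPartParams


def toy_params(rng, spec, max_var=0.6):
    """Random parameters at realistic magnitudes (PSD by construction)."""
    q = spec.q
    v = rng.uniform(0.05, max_var, q)
    psi = np.diag(v)
    for i, j in spec.free_psi_pairs():
        r = rng.uniform(-0.6, 0.6)
        psi[i, j] = psi[j, i] = r * np.sqrt(v[i] * v[j])
    if np.min(np.linalg.eigvalsh(psi)) < 1e-4:
        psi = np.diag(v)
    mu = rng.normal(0.5, 0.4, q)
    th = rng.uniform(0.4, 1.5, spec.n_occasions)
    return TwoPartParams(mu, psi, th, np.array([rng.normal(0.0, 0.2)]))


def toy_data(rng, n=6, T=3, missing=0.2, covariate=True):
    """Small random two-part dataset with mixed missingness."""
    b = rng.integers(0, 2, size=(n, T)).astype(float)
    c = np.where(b == 1, rng.normal(1.0, 1.0, size=(n, T)), np.nan)
    drop = rng.random((n, T)) < missing
    b[drop] = np.nan
    c[drop] = np.nan
    cov = pd.DataFrame({"x": rng.normal(0.0, 1.0, n)}) if covariate else None
    return TwoPartData(b, c, covariates=cov)


@pytest.fixture
def rng():
    return np.random.default_rng(20190702)


@pytest.fixture
def spec():
    return GrowthSpec()
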