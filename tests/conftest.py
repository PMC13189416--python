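"""Shared fixtures: the synthetic study dataset and its pipeline products.

Session-scoped so the expensive NMF runs are shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from temponmf import io_normalize as ion
from temponmf import nmf_behaviors as nmf
from temponmf import synthetic_data as synth

#: Stopping threshold used for fixture-scale fits: chosen so the
#: optimization is converged rather than stopped on an early plateau
#: (the matrix here is ~20x fewer genes than a genome-scale one, so the
#: Frobenius gap and its per-iteration changes are correspondingly smaller).
FIXTURE_THETA = 1e-4


@pytest.fixture(scope="session")
def dataset() -> synth.SyntheticDataset:
    """Default study fixture: 2,000 genes, 5 behaviors, 3 replicates, CV 0.1."""
    return synth.make_dataset()


@pytest.fixture(scope="session")
def pipeline(dataset):
    """Normalized, filtered, replicate-averaged and max-scaled products."""
    s = ion.size_factors(dataset.expression)
    norm = ion.normalize(dataset.expression, s)
    filt = ion.filter_low_expressed(norm)
    tm = ion.average_replicates(filt, dataset.sheet, share_baseline=False)
    scaled = ion.max_scale(tm)
    return {"size_factors": s, "filtered": filt, "tm": tm, "scaled": scaled}


@pytest.fixture(scope="session")
def fitted_model(pipeline):
    """Converged NMF fit of the fixture at the true rank."""
    return nmf.fit(pipeline["scaled"], nmf.NMFConfig(M=5, seed=1, theta=FIXTURE_THETA))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240417)


def random_expression(rng: np.random.Generator, g: int = 30, n: int = 6) -> pd.DataFrame:
    """Strictly positive lognormal expression table."""
    vals = rng.lognormal(mean=2.0, sigma=1.0, size=(g, n))
    return pd.DataFrame(
        vals,
        index=pd.Index([f"g{i}" for i in range(g)], name="gene_id"),
        columns=[f"s{j}" for j in range(n)],
    )
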