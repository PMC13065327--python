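import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from baitquant import SampleDesign, SimulationConfig, simulate_experiment


def make_design(
    conditions=("mitotic_metaphase", "prophase", "metaphase_I", "metaphase_II"),
    n_replicates=3,
    tags=("tag", "no_tag"),
    fractions=("N", "PE"),
):
    rows = [
        {
            "sample_id": f"{c}.{t}.{f}.r{r}",
            "condition": c,
            "replicate": r,
            "tag": t,
            "fraction": f,
        }
        for c in conditions
        for t in tags
        for f in fractions
        for r in range(1, n_replicates + 1)
    ]
    return SampleDesign(pd.DataFrame(rows))


@pytest.fixture
def full_design():
    """The study layout: 4 conditions x 3 replicates x {tag,no_tag} x {N,PE}."""
    return make_design()


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated experiment, shared across read-only tests."""
    return simulate_experiment(SimulationConfig(seed=11))


def random_matrix(rng, n_rows=30, n_cols=8, missing=0.2, prefix="P"):
    """Random positive intensity frame with Bernoulli missingness."""
    vals = 10 ** rng.uniform(4, 9, size=(n_rows, n_cols))
    mask = rng.random((n_rows, n_cols)) < missing
    vals = np.where(mask, np.nan, vals)
    return pd.DataFrame(
        vals,
        index=[f"{prefix}{i:03d}" for i in range(n_rows)],
        columns=[f"s{j}" for j in range(n_cols)],
    )
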