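import numpy as np
import pytest

from omicflux import (
    normalize_subsystem_names,
    set_objective_pair,
    split_multi_subsystems,
)
from omicflux import fixtures as fx


@pytest.fixture(scope="session")
def toy_model():
    """Raw toy network, before subsystem curation / objective selection."""
    return fx.make_toy_model()


@pytest.fixture(scope="session")
def curated_model(toy_model):
    """Curated toy network with the biomass / ATP-maintenance objective pair."""
    m = split_multi_subsystems(normalize_subsystem_names(toy_model))
    return set_objective_pair(
        m, "Biomass synthesis (carbon limited)", "ATP maintenance requirment"
    )


@pytest.fixture(scope="session")
def condition_specs():
    return fx.builtin_condition_bounds()


@pytest.fixture(scope="session")
def transcriptome(toy_model):
    return fx.make_synthetic_transcriptome(toy_model, fx.FixtureConfig(seed=0))


@pytest.fixture(scope="session")
def transcript_fc(transcriptome):
    """Conditions x genes fold-change matrix from the two synthetic tables."""
    import pandas as pd

    from omicflux.omics import rpkm_to_foldchange

    ds1, ds2 = transcriptome
    controls = [c for c in ds1.columns if c.startswith("control_")]
    fc1 = rpkm_to_foldchange(
        ds1.set_index("gene_id"), controls, [c for c in fx.CONDITIONS if c in ds1]
    )
    fc2 = rpkm_to_foldchange(
        ds2.set_index("gene_id"), controls, [c for c in fx.CONDITIONS if c in ds2]
    )
    return pd.concat([fc1, fc2], axis=1)[fx.CONDITIONS].T


def planted_lasso_problem(seed, n=12, n_noise=50, n_modules=5, idio=0.3, noise=0.1):
    """Growth-rate regression fixture: 3 planted predictors, module-structured noise.

    The noise predictors mimic co-regulated transcript modules (a few
    shared factors plus idiosyncratic variation); the planted predictors
    carry coefficients (2, -2, 2).
    """
    rng = np.random.default_rng(seed)
    planted = rng.normal(size=(n, 3))
    factors = rng.normal(size=(n, n_modules))
    loadings = rng.integers(0, n_modules, size=n_noise)
    noise_block = factors[:, loadings] + idio * rng.normal(size=(n, n_noise))
    X = np.hstack([planted, noise_block])
    y = 2.0 * X[:, 0] - 2.0 * X[:, 1] + 2.0 * X[:, 2] + noise * rng.normal(size=n)
    return X, y
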