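import numpy as np
import pytest

from fluxgpr import gpr, synthetic
from fluxgpr.schema import default_schema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_table(schema):
    """150-sample synthetic predictor/flux table (fixed seed)."""
    preds = synthetic.sample_predictors(150, schema, seed=42)
    fluxes = synthetic.generate_fluxes(preds, seed=43)
    return preds, fluxes


@pytest.fixture(scope="session")
def fitted_gpp_model(small_table):
    """A GP fitted on the 150-sample table (shared across tests)."""
    preds, fluxes = small_table
    tm = gpr.TrainingMatrix.from_raw(
        preds.to_numpy(), fluxes["GPP"].to_numpy(),
        flux_variable="GPP", predictor_names=tuple(preds.columns),
    )
    return gpr.fit(tm, gpr.FitConfig(restarts=2, seed=0, maxiter=100))


@pytest.fixture(scope="session")
def small_scene():
    """A compact synthetic scene with ground truth (fixed seed)."""
    return synthetic.generate_grid_scene(
        extent=(3.0, 3.0), resolution_lai=0.1, climate_ratio=3,
        time_steps=12, seed=7,
    )


def random_gp_instance(rng, n, D, noise=0.1):
    """Draw a small GP training set with known hyperparameters."""
    X = rng.uniform(-2, 2, size=(n, D))
    hyp = gpr.Hyperparameters(
        signal_var=float(rng.uniform(0.5, 2.0)),
        lengthscales=rng.uniform(0.3, 3.0, size=D),
        noise_var=float(rng.uniform(0.01, 0.5)) if noise else 0.0,
    )
    K = gpr.kernel_matrix(X, X, hyp) + (hyp.noise_var + 1e-10) * np.eye(n)
    y = np.linalg.cholesky(K) @ rng.standard_normal(n)
    tm = gpr.TrainingMatrix(X, y, np.zeros(D), np.ones(D), 0.0, 1.0)
    return tm, hyp
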