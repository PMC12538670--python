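"""Portable JSON serialization of fitted GP flux models.

The export is self-describing: predictor schema, hyperparameters, the
standardization constants, the (standardized) training inputs and targets,
the precomputed weight vector alpha, and the diagonal jitter used during
factorization.  Any runtime that can evaluate an RBF kernel, a Cholesky
factorization and a triangular solve can reproduce the native predictions
from this file alone (see ``fluxgpr.gpr.standalone_predict``), which is the
contract that lets the models be deployed outside this package (e.g. in a
cloud map-reduce platform).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.linalg import cho_solve

from .. import gpr
from ..schema import PredictorSchema

__all__ = ["export_model_file", "import_model_file", "model_record",
           "FORMAT_VERSION"]

FORMAT_VERSION = 1


def model_record(model: gpr.TrainedGPR,
                 schema: PredictorSchema | None = None) -> dict:
    """The JSON-ready dict representation of a fitted model."""
    tr = model.training
    hyp = model.hyperparameters
    rec = {
        "format": "fluxgpr-model",
        "version": FORMAT_VERSION,
        "flux_variable": tr.flux_variable,
        "schema": schema.to_dict() if schema is not None else [
            {"name": n} for n in tr.predictor_names
        ],
        "theta": {
            "signal_var": hyp.signal_var,
            "lengthscales": hyp.lengthscales.tolist(),
            "noise_var": hyp.noise_var,
        },
        "x_mean": tr.x_mean.tolist(),
        "x_scale": tr.x_scale.tolist(),
        "y_mean": tr.y_mean,
        "y_scale": tr.y_scale,
        "X_train": tr.X.tolist(),
        "y_train": tr.y.tolist(),
        "alpha": model.alpha.tolist(),
        "jitter": model.jitter,
        "log_marginal_likelihood": model.log_marginal_likelihood,
    }
    return rec


def export_model_file(model: gpr.TrainedGPR, path: str | Path,
                      schema: PredictorSchema | None = None) -> None:
    """Write a fitted model to a self-describing JSON file."""
    Path(path).write_text(json.dumps(model_record(model, schema)))


def import_model_file(path: str | Path) -> gpr.TrainedGPR:
    """Load an exported model; predictions match the original to <= 1e-10.

    The Cholesky factor is rebuilt from the stored inputs, hyperparameters
    and jitter — the identical matrix, hence the identical factor.
    """
    try:
        rec = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"{path}: truncated or corrupt model file: {exc}") from exc
    if not isinstance(rec, dict) or rec.get("format") != "fluxgpr-model":
        raise ValueError(f"{path}: not a fluxgpr model export")
    if rec.get("version") != FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {rec.get('version')!r} does not "
            f"match supported version {FORMAT_VERSION}"
        )
    for key in ("theta", "x_mean", "x_scale", "y_mean", "y_scale", "X_train",
                "alpha"):
        if key not in rec:
            raise ValueError(f"{path}: model file missing field {key!r}")

    hyp = gpr.Hyperparameters(
        signal_var=float(rec["theta"]["signal_var"]),
        lengthscales=np.asarray(rec["theta"]["lengthscales"], dtype=float),
        noise_var=float(rec["theta"]["noise_var"]),
    )
    X = np.asarray(rec["X_train"], dtype=float)
    if "y_train" in rec:
        y = np.asarray(rec["y_train"], dtype=float)
    else:
        y = None  # reconstructed below from alpha
    names = tuple(e.get("name", "") for e in rec.get("schema", []))
    jitter = float(rec.get("jitter", 0.0))
    alpha = np.asarray(rec["alpha"], dtype=float)

    n = X.shape[0]
    K = gpr.kernel_matrix(X, X, hyp)
    Kn = K + (hyp.noise_var + jitter) * np.eye(n)
    from scipy.linalg import cholesky

    L = cholesky(Kn, lower=True)
    if y is None:
        y = Kn @ alpha

    training = gpr.TrainingMatrix(
        X=X, y=y,
        x_mean=np.asarray(rec["x_mean"], dtype=float),
        x_scale=np.asarray(rec["x_scale"], dtype=float),
        y_mean=float(rec["y_mean"]), y_scale=float(rec["y_scale"]),
        flux_variable=rec.get("flux_variable", ""),
        predictor_names=names,
    )
    return gpr.TrainedGPR(
        hyperparameters=hyp,
        training=training,
        alpha=alpha,
        chol_L=L,
        jitter=jitter,
        log_marginal_likelihood=float(rec.get("log_marginal_likelihood", np.nan)),
    )
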