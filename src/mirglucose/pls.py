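"""Single-response partial least-squares regression (NIPALS-PLS1).

PLS projects the (mean-centered) spectra onto a small number of latent
variables chosen to maximise covariance with the (centered) concentration,
then regresses on the scores.  For a single response the NIPALS weight is
available in closed form each round — ``w ∝ X^T y`` — so no inner iteration
is needed: per component, score ``t = X w``, x-loading ``p = X^T t / t^T t``,
y-loading ``q = y^T t / t^T t``, then X and y are deflated by the rank-one
score contribution.  Component extraction stops early (with a warning) when
the residual score energy falls below ``1e-12`` of the initial squared
Frobenius norm of X, so numerical noise is never amplified into spurious
components.

Sign convention: each weight vector's largest-magnitude element is forced
positive, making fitted models reproducible across BLAS implementations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .preprocess import FittedPreprocessor, PreprocessSpec, apply as preproc_apply, fit_apply
from .spectra import SpectraSet, WavenumberGrid

__all__ = [
    "PLSModel",
    "Calibration",
    "RankDeficiencyWarning",
    "fit",
    "regression_vector",
    "predict_centered",
    "predict",
    "calibrate",
    "predict_set",
    "save_calibration",
    "load_calibration",
]


class RankDeficiencyWarning(UserWarning):
    """Emitted when NIPALS stops before the requested number of components."""


@dataclass(frozen=True)
class PLSModel:
    """Weights, loadings and centering statistics of a fitted PLS1 model.

    Matrices are wavenumbers x components; ``scores`` (samples x components)
    are retained for diagnostics such as orthogonality checks.
    """

    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    x_mean: np.ndarray
    y_mean: float

    @property
    def n_components(self) -> int:
        return int(self.weights.shape[1])

    @property
    def regression_vector(self) -> np.ndarray:
        return regression_vector(self)


def fit(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    x_mean: Optional[np.ndarray] = None,
    y_mean: float = 0.0,
) -> PLSModel:
    """Fit NIPALS-PLS1 on centered data.

    ``X`` and ``y`` must already be centered (the preprocessing stage owns
    centering); the means may be passed along for bookkeeping so the model
    can predict raw inputs later.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("X rows and y length differ")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(
            f"n_lv must lie in [1, min(n-1, p)] = [1, {min(n - 1, p)}], got {n_lv}"
        )
    tol = 1e-12 * float(np.sum(X**2))
    Xd = X.copy()
    yd = y.copy()
    W, P, Q, T = [], [], [], []
    for _ in range(n_lv):
        w = Xd.T @ yd
        wn = np.linalg.norm(w)
        if wn == 0.0 or not np.isfinite(wn):
            break
        w /= wn
        if w[int(np.argmax(np.abs(w)))] < 0:
            w = -w
        t = Xd @ w
        tt = float(t @ t)
        if tt <= tol:
            break
        p_vec = Xd.T @ t / tt
        q = float(yd @ t) / tt
        Xd -= np.outer(t, p_vec)
        yd -= t * q
        W.append(w)
        P.append(p_vec)
        Q.append(q)
        T.append(t)
    if len(W) < n_lv:
        warnings.warn(
            f"NIPALS extracted only {len(W)} of {n_lv} requested components "
            "(residual rank exhausted)",
            RankDeficiencyWarning,
            stacklevel=2,
        )
    if not W:
        raise ValueError("no PLS component could be extracted (X^T y is zero)")
    return PLSModel(
        weights=np.column_stack(W),
        x_loadings=np.column_stack(P),
        y_loadings=np.array(Q),
        scores=np.column_stack(T),
        x_mean=np.zeros(p) if x_mean is None else np.asarray(x_mean, dtype=float),
        y_mean=float(y_mean),
    )


def regression_vector(model: PLSModel, n_lv: Optional[int] = None) -> np.ndarray:
    """Regression vector b = W (P^T W)^{-1} q using the first ``n_lv``
    components (all by default), so that yhat = Xc b + y_mean."""
    k = model.n_components if n_lv is None else int(n_lv)
    if not 1 <= k <= model.n_components:
        raise ValueError(f"n_lv must lie in [1, {model.n_components}]")
    W = model.weights[:, :k]
    P = model.x_loadings[:, :k]
    q = model.y_loadings[:k]
    return W @ np.linalg.solve(P.T @ W, q)


def predict_centered(
    model: PLSModel, X_centered: np.ndarray, n_lv: Optional[int] = None
) -> np.ndarray:
    """Predict (uncentered) responses from already-centered spectra."""
    b = regression_vector(model, n_lv)
    return np.asarray(X_centered, dtype=float) @ b + model.y_mean


def predict(
    model: PLSModel,
    sset: SpectraSet,
    preprocessor: FittedPreprocessor,
    n_lv: Optional[int] = None,
) -> np.ndarray:
    """Predict glucose (mg/dL) for a SpectraSet through a fitted
    preprocessor (row operators + training-mean centering)."""
    return predict_centered(model, preproc_apply(preprocessor, sset), n_lv)


# ---------------------------------------------------------------------------
# Calibration bundle: preprocessing + PLS in one serialisable object
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Calibration:
    """A fitted preprocessor and PLS model trained together."""

    preprocessor: FittedPreprocessor
    model: PLSModel
    n_lv: int


def calibrate(train: SpectraSet, spec: PreprocessSpec, n_lv: int) -> Calibration:
    """Fit preprocessing statistics and a PLS1 model on a training set."""
    fp, Xc = fit_apply(spec, train)
    model = fit(
        Xc,
        train.glucose - fp.y_mean,
        n_lv,
        x_mean=fp.column_means,
        y_mean=fp.y_mean,
    )
    return Calibration(preprocessor=fp, model=model, n_lv=min(n_lv, model.n_components))


def predict_set(cal: Calibration, sset: SpectraSet) -> np.ndarray:
    """Predict glucose (mg/dL) for a SpectraSet with a saved calibration."""
    return predict(cal.model, sset, cal.preprocessor, cal.n_lv)


def save_calibration(cal: Calibration, path: str) -> None:
    """Serialise a calibration to JSON (full precision) so a reloaded model
    re-predicts bit-identically."""
    payload = {
        "format": "mirglucose-calibration-v1",
        "n_lv": cal.n_lv,
        "preprocess": cal.preprocessor.spec.to_dict(),
        "grid": cal.preprocessor.grid.values.tolist(),
        "column_means": cal.preprocessor.column_means.tolist(),
        "y_mean": cal.preprocessor.y_mean,
        "weights": cal.model.weights.tolist(),
        "x_loadings": cal.model.x_loadings.tolist(),
        "y_loadings": cal.model.y_loadings.tolist(),
        "scores": cal.model.scores.tolist(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_calibration(path: str) -> Calibration:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != "mirglucose-calibration-v1":
        raise ValueError(f"{path} is not a saved calibration")
    fp = FittedPreprocessor(
        spec=PreprocessSpec.from_dict(payload["preprocess"]),
        grid=WavenumberGrid(np.array(payload["grid"])),
        column_means=np.array(payload["column_means"]),
        y_mean=float(payload["y_mean"]),
    )
    model = PLSModel(
        weights=np.array(payload["weights"]),
        x_loadings=np.array(payload["x_loadings"]),
        y_loadings=np.array(payload["y_loadings"]),
        scores=np.array(payload["scores"]),
        x_mean=np.array(payload["column_means"]),
        y_mean=float(payload["y_mean"]),
    )
    return Calibration(preprocessor=fp, model=model, n_lv=int(payload["n_lv"]))
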