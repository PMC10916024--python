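"""Background functional-impact model: a normal GLM with identity link.

Observed per-gene FIS totals y_g are regressed on the standardized
covariates, y_g = x_g^T beta + eps, eps ~ N(0, sigma0^2). With an identity
link and normal errors the maximum-likelihood solution is ordinary least
squares; sigma0 is the ML estimate sqrt(RSS / n). The fitted mean x_g^T beta
is each gene's background FIS (BFIS).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["BackgroundModel", "fit_glm", "predict_bfis"]

_SIGMA0_FLOOR = 1e-8


@dataclass(frozen=True)
class BackgroundModel:
    """Fitted background model: intercept-first coefficients and residual sd."""

    beta: np.ndarray  # length p + 1, intercept first
    sigma0: float
    feature_names: tuple[str, ...]
    n_fit: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        if len(self.beta) != len(self.feature_names) + 1:
            raise ValueError("beta length must be number of features + 1")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "feature_names": list(self.feature_names),
            "beta": self.beta.tolist(),
            "sigma0": self.sigma0,
            "n_fit": self.n_fit,
        }, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "BackgroundModel":
        d = json.loads(Path(path).read_text())
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            sigma0=float(d["sigma0"]),
            feature_names=tuple(d["feature_names"]),
            n_fit=int(d["n_fit"]),
        )


def _collinear_columns(design: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name the columns involved in a rank deficiency via QR pivoting."""
    from scipy.linalg import qr

    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    dropped = piv[np.sum(diag > tol):]
    labels = ["intercept"] + list(names)
    return [labels[i] for i in sorted(dropped)]


def fit_glm(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str] | None = None,
    unbiased_variance: bool = False,
) -> BackgroundModel:
    """Fit the normal-GLM background model by (closed-form) maximum likelihood.

    ``X`` is the genes x p standardized covariate matrix without an
    intercept column; one is prepended. ``sigma0`` divides the RSS by n
    (ML) or by n - p - 1 with ``unbiased_variance``. A numerically zero
    residual triggers a degenerate-fit warning and sigma0 is floored so
    downstream p-values stay defined.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of genes")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; impute before fitting")
    n, p = X.shape
    if feature_names is None:
        feature_names = tuple(f"x{i + 1}" for i in range(p))
    feature_names = tuple(feature_names)
    if len(feature_names) != p:
        raise ValueError("feature_names length does not match X columns")
    if n <= p + 1:
        raise ValueError(f"need more genes ({n}) than parameters ({p + 1}) to fit")

    design = np.hstack([np.ones((n, 1)), X])
    if np.linalg.matrix_rank(design) < p + 1:
        raise ValueError(
            f"rank-deficient design; collinear columns: {_collinear_columns(design, feature_names)}"
        )
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((y - design @ beta) ** 2))
    dof = n - p - 1 if unbiased_variance else n
    sigma0 = float(np.sqrt(rss / dof))
    if rss < 1e-12:
        warnings.warn(
            "degenerate fit: residual sum of squares is numerically zero; "
            f"sigma0 floored at {_SIGMA0_FLOOR}", RuntimeWarning,
        )
        sigma0 = max(sigma0, _SIGMA0_FLOOR)
    logger.info("fit_glm: n=%d p=%d sigma0=%.4g", n, p, sigma0)
    return BackgroundModel(beta=beta, sigma0=sigma0, feature_names=feature_names, n_fit=n)


def predict_bfis(
    model: BackgroundModel,
    x: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> np.ndarray | float:
    """Background FIS x^T beta (intercept included) for one vector or a matrix.

    When ``feature_names`` is given it must match the fit order exactly.
    """
    if feature_names is not None and tuple(feature_names) != model.feature_names:
        raise ValueError(
            f"feature names {tuple(feature_names)} do not match the fitted "
            f"model's {model.feature_names}"
        )
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, got {X.shape[1]}"
        )
    pred = model.beta[0] + X @ model.beta[1:]
    return float(pred[0]) if single else pred
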