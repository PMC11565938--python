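"""Gaussian-process surrogate over a mixed parameter domain.

Parameter vectors are encoded into the unit box: non-binary coordinates are
min-max scaled by the active search domain, binary coordinates enter as 0/1.
A single ARD Matern-5/2 kernel acts on the encoding (on a 0/1 coordinate the
Matern value is a fixed monotone function of coordinate agreement, so binary
dimensions behave like a categorical-overlap factor).  Targets are
standardized internally (``normalize_y``); predictions are returned on the
original loss scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Kernel, Matern

from .param_space import ParamVector, SearchDomain

__all__ = ["Surrogate", "fit_surrogate", "encode_points"]


def encode_points(
    thetas: Sequence[ParamVector] | np.ndarray, domain: SearchDomain
) -> np.ndarray:
    """Map native-scale parameter vectors into the unit box."""
    X = np.asarray(
        [t.as_array() if isinstance(t, ParamVector) else t for t in thetas],
        dtype=float,
    )
    lo, hi = domain.lo_array(), domain.hi_array()
    span = np.maximum(hi - lo, 1e-12)
    return (X - lo) / span


@dataclass
class Surrogate:
    """Fitted GP exposing the posterior mean/std on the loss scale."""

    gpr: GaussianProcessRegressor
    domain: SearchDomain

    def posterior(self, thetas) -> tuple[np.ndarray, np.ndarray]:
        X = encode_points(np.atleast_2d(_to_matrix(thetas)), self.domain)
        mean, std = self.gpr.predict(X, return_std=True)
        return mean, std

    def posterior_mean(self, theta: ParamVector) -> float:
        mean, _ = self.posterior([theta])
        return float(mean[0])

    @property
    def kernel_(self) -> Kernel:
        return self.gpr.kernel_


def _to_matrix(thetas) -> np.ndarray:
    if isinstance(thetas, np.ndarray):
        return thetas
    return np.asarray(
        [t.as_array() if isinstance(t, ParamVector) else np.asarray(t) for t in thetas]
    )


def fit_surrogate(
    trace,
    domain: SearchDomain,
    optimize: bool = True,
    kernel: Kernel | None = None,
    seed: int = 0,
    alpha: float = 1e-8,
) -> Surrogate:
    """Fit a GP to a Trace's (theta, y) records over the given domain.

    ``optimize=False`` reuses a previously fitted ``kernel`` without
    re-optimizing hyperparameters (used between periodic refits during BO).
    The jitter ``alpha`` is increased tenfold on Cholesky failure, up to
    1e-2.
    """
    records = list(trace.records) if hasattr(trace, "records") else list(trace)
    if len(records) < 2:
        raise ValueError("need at least 2 evaluations to fit a surrogate")
    X = encode_points([r.theta for r in records], domain)
    y = np.asarray([r.y for r in records], dtype=float)
    if np.allclose(X, X[0]):
        raise ValueError("degenerate trace: all parameter vectors identical")
    d = X.shape[1]
    if kernel is None:
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
            length_scale=np.full(d, 0.5),
            length_scale_bounds=(1e-2, 1e2),
            nu=2.5,
        )
    cur_alpha = alpha
    last_err: Exception | None = None
    while cur_alpha <= 1e-2:
        gpr = GaussianProcessRegressor(
            kernel=kernel,
            alpha=cur_alpha,
            normalize_y=True,
            optimizer="fmin_l_bfgs_b" if optimize else None,
            n_restarts_optimizer=1 if optimize else 0,
            random_state=seed,
        )
        try:
            import warnings

            from sklearn.exceptions import ConvergenceWarning

            with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
                # hyperparameters pinned at their bounds are acceptable here
                warnings.simplefilter("ignore", ConvergenceWarning)
                gpr.fit(X, y)
            return Surrogate(gpr=gpr, domain=domain)
        except np.linalg.LinAlgError as err:  # ill-conditioned kernel matrix
            last_err = err
            cur_alpha *= 10.0
    raise RuntimeError(f"GP fit failed even with heavy jitter: {last_err}")
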