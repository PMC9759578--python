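"""Sparse partial-correlation connectomes via the graphical LASSO.

One connectome is estimated per (subject, session, scan context) from the
retained (uncensored) frames of the cleaned, concatenated task timeseries.
The estimator is the L1-penalized Gaussian maximum-likelihood precision
matrix (penalty on off-diagonal entries only, applied to the sample
correlation matrix so the penalty is scale-free), converted to signed
partial correlations ``w_ij = -omega_ij / sqrt(omega_ii * omega_jj)``.
Both positive and negative partial correlations are retained; a common
penalty ``lambda = 0.1`` is the default throughout.

The solver is scikit-learn's coordinate-descent graphical lasso; every
estimate can be verified against the Karush-Kuhn-Tucker optimality
conditions with :func:`kkt_residual`, which is solver-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import pinvh
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

__all__ = [
    "FunctionalConnectome",
    "estimate_precision",
    "precision_to_partial_correlation",
    "estimate_connectome",
    "kkt_residual",
]

DEFAULT_LAMBDA = 0.1


@dataclass(frozen=True)
class FunctionalConnectome:
    """Signed, sparse, symmetric partial-correlation network.

    ``partial_corr`` has zero diagonal and entries in [-1, 1]; ``lam`` is
    the graphical-LASSO penalty used; ``n_frames_used`` the number of
    retained frames that entered the sample correlation.
    """

    partial_corr: np.ndarray
    lam: float
    n_frames_used: int
    roi_ids: tuple
    network_labels: tuple

    @property
    def n_rois(self) -> int:
        return self.partial_corr.shape[0]

    def n_edges(self, tol: float = 0.0) -> int:
        """Number of nonzero off-diagonal entries (undirected count)."""
        off = self.partial_corr[np.triu_indices(self.n_rois, k=1)]
        return int(np.sum(np.abs(off) > tol))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.partial_corr, index=self.roi_ids, columns=self.roi_ids)


def _sample_correlation(timeseries: np.ndarray) -> np.ndarray:
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be a 2-D region-by-time array")
    n_rois, t = ts.shape
    if t <= 2:
        raise ValueError(f"need more than 2 retained frames, got {t}")
    sd = ts.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"regions with zero variance cannot be correlated: {bad.tolist()}")
    S = np.corrcoef(ts)
    # guard tiny asymmetries from accumulation order
    return (S + S.T) / 2.0


def estimate_precision(
    timeseries: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    *,
    tol: float = 1e-4,
    enet_tol: float = 1e-8,
    max_iter: int = 200,
    kkt_tol: float = 1e-2,
) -> np.ndarray:
    """L1-penalized precision matrix of region-by-time data (retained frames).

    The working covariance is the sample correlation of the input, so the
    penalty is dimensionless and comparable across subjects.  ``lam = 0``
    returns the unpenalized maximum-likelihood precision (inverse sample
    correlation), which requires more frames than regions.  ``p > n`` is
    permitted for ``lam > 0`` (the penalty regularizes the fit) but noted
    with a warning.
    """
    ts = np.asarray(timeseries, dtype=float)
    S = _sample_correlation(ts)
    n_rois, t = ts.shape
    if lam < 0:
        raise ValueError("penalty lambda must be >= 0")
    if lam == 0:
        if t <= n_rois:
            raise ValueError(
                "lambda = 0 requires more retained frames than regions "
                f"(got {t} frames for {n_rois} regions)"
            )
        return pinvh(S)
    if t < n_rois:
        warnings.warn(
            f"fewer retained frames ({t}) than regions ({n_rois}); "
            "relying on the L1 penalty for identifiability",
            stacklevel=2,
        )
    precision = None
    warm = None
    try:
        _, precision = _sk_graphical_lasso(
            S, alpha=lam, tol=tol, enet_tol=enet_tol, max_iter=max_iter
        )
        precision = (precision + precision.T) / 2.0
        if kkt_residual(S, precision, lam) > kkt_tol:
            warm, precision = precision, None
    except FloatingPointError:
        precision = None
    if precision is None:
        # coordinate descent struggles when post-censoring rank loss
        # drives correlations to +-1; the ADMM splitting below only ever
        # eigendecomposes, so it is robust to singular input
        warnings.warn(
            "coordinate-descent graphical lasso failed; falling back to "
            "the ADMM solver",
            stacklevel=2,
        )
        precision = _admm_glasso(S, lam, init=warm, kkt_stop=min(kkt_tol, 1e-4))
    resid = kkt_residual(S, precision, lam)
    if resid > kkt_tol:
        raise RuntimeError(
            f"graphical lasso did not reach optimality (KKT residual {resid:.3g}); "
            "increase max_iter or tighten tol"
        )
    return precision


def _admm_glasso(
    S: np.ndarray,
    lam: float,
    rho: float = 1.0,
    max_iter: int = 10_000,
    init: np.ndarray | None = None,
    kkt_stop: float = 1e-6,
) -> np.ndarray:
    """Graphical lasso by ADMM splitting (off-diagonal penalty only).

    Theta-update solves ``-logdet + tr(S Theta) + rho/2 ||Theta - Z + U||^2``
    in closed form through the eigendecomposition of ``rho (Z - U) - S``;
    Z-update soft-thresholds the off-diagonal.  Slower than coordinate
    descent but defined for any symmetric working matrix, including the
    exactly singular correlations short censored runs produce.  Stops as
    soon as the periodically evaluated KKT residual of the (positive
    definite) Theta iterate falls below ``kkt_stop``.
    """
    n = S.shape[0]
    Z = np.eye(n) if init is None else init.copy()
    U = np.zeros((n, n))
    for it in range(1, max_iter + 1):
        M = rho * (Z - U) - S
        ew, ev = np.linalg.eigh(M)
        theta_ew = (ew + np.sqrt(ew**2 + 4.0 * rho)) / (2.0 * rho)
        Theta = (ev * theta_ew) @ ev.T
        A = Theta + U
        Z = np.sign(A) * np.maximum(np.abs(A) - lam / rho, 0.0)
        np.fill_diagonal(Z, np.diag(A))
        U = U + Theta - Z
        if it % 50 == 0:
            Zs = (Z + Z.T) / 2.0
            # the soft-thresholded iterate carries the exact zeros the
            # optimality check needs, but is only PD near convergence
            if np.linalg.eigvalsh(Zs)[0] > 0 and kkt_residual(S, Zs, lam) < kkt_stop:
                break
    return (Z + Z.T) / 2.0


def kkt_residual(S: np.ndarray, precision: np.ndarray, lam: float) -> float:
    """Maximum violation of the graphical-LASSO optimality conditions.

    For the objective ``-logdet(P) + tr(S P) + lam * sum_{i!=j} |P_ij|``
    the stationarity conditions are, with ``G = S - P^{-1}``:

    * diagonal: ``G_ii = 0``;
    * nonzero off-diagonal: ``G_ij + lam * sign(P_ij) = 0``;
    * zero off-diagonal: ``|G_ij| <= lam``.

    Returns the largest absolute violation; independent of how the
    precision was produced, so it verifies any solver.
    """
    S = np.asarray(S, dtype=float)
    P = np.asarray(precision, dtype=float)
    G = S - np.linalg.inv(P)
    n = P.shape[0]
    off = ~np.eye(n, dtype=bool)
    nz = off & (P != 0)
    z = off & (P == 0)
    resid = float(np.max(np.abs(np.diag(G))))
    if nz.any():
        resid = max(resid, float(np.max(np.abs(G[nz] + lam * np.sign(P[nz])))))
    if z.any():
        resid = max(resid, float(np.max(np.maximum(np.abs(G[z]) - lam, 0.0))))
    return resid


def precision_to_partial_correlation(
    precision: np.ndarray,
    roi_ids: Sequence | None = None,
    network_labels: Sequence[str] | None = None,
    lam: float = float("nan"),
    n_frames_used: int = 0,
) -> FunctionalConnectome:
    """Convert a precision matrix to a signed partial-correlation network.

    ``w_ij = -omega_ij / sqrt(omega_ii * omega_jj)`` for ``i != j``; the
    diagonal is set to zero (a region's partial correlation with itself
    is not defined as an edge).  Signs are preserved exactly.
    """
    P = np.asarray(precision, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("precision must be square")
    if not np.allclose(P, P.T, atol=1e-8):
        raise ValueError("precision must be symmetric")
    d = np.diag(P)
    if np.any(d <= 0):
        raise ValueError("precision diagonal must be strictly positive")
    denom = np.sqrt(np.outer(d, d))
    W = -P / denom
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2.0
    n = P.shape[0]
    if roi_ids is None:
        roi_ids = tuple(range(n))
    if network_labels is None:
        network_labels = ("",) * n
    return FunctionalConnectome(
        partial_corr=W,
        lam=float(lam),
        n_frames_used=int(n_frames_used),
        roi_ids=tuple(roi_ids),
        network_labels=tuple(network_labels),
    )


def estimate_connectome(
    timeseries: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    roi_ids: Sequence | None = None,
    network_labels: Sequence[str] | None = None,
    **solver_kwargs,
) -> FunctionalConnectome:
    """Retained-frame timeseries -> signed sparse partial-correlation network."""
    precision = estimate_precision(timeseries, lam, **solver_kwargs)
    return precision_to_partial_correlation(
        precision,
        roi_ids=roi_ids,
        network_labels=network_labels,
        lam=lam,
        n_frames_used=np.asarray(timeseries).shape[1],
    )
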