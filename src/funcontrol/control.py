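"""Network controllability of a functional connectome.

The connectome is treated as the coupling matrix of a discrete linear
time-invariant system ``x(t+1) = A x(t) + B u(t)``: ``x`` is the
multi-region BOLD signal, ``A`` the (stabilized) connectome, and ``u``
an exogenous input delivered through ``B``.  Two node-level metrics are
computed for single-region inputs (``B = e_i``):

* **Average controllability** — the trace of the infinite-horizon
  controllability Gramian ``W_i = sum_t A^t b_i b_i' (A')^t``, i.e. the
  total output energy the system produces in response to a unit impulse
  at region ``i``.  High values mark regions whose input moves the whole
  system strongly.
* **Modal controllability** — ``phi_i = sum_j (1 - lambda_j^2) v_ij^2``
  over the eigenmodes ``(lambda_j, v_j)`` of the symmetric ``A``; high
  values mark regions able to excite the fast-decaying, hard-to-reach
  modes of the system.

Network-level metrics are unweighted means of the node values within
each functional network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla

__all__ = [
    "ControlSystem",
    "ControllabilityProfile",
    "stabilize",
    "average_controllability",
    "modal_controllability",
    "network_controllability",
    "controllability_profile",
]

_SYM_ATOL = 1e-10


@dataclass(frozen=True)
class ControlSystem:
    """A stabilized symmetric system matrix with provenance of the scaling.

    ``A`` has spectral radius < 1 so the discrete-time controllability
    Gramian exists.  ``normalization`` records the scheme and the factor
    applied to the raw connectome.
    """

    A: np.ndarray
    normalization: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvalsh(self.A))))


@dataclass(frozen=True)
class ControllabilityProfile:
    """Per-region and per-network controllability for one connectome."""

    roi_ids: tuple
    network_labels: tuple
    avg_ctrb: np.ndarray
    modal_ctrb: np.ndarray
    network_avg: dict
    network_modal: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": self.roi_ids,
                "network": self.network_labels,
                "avg_ctrb": self.avg_ctrb,
                "modal_ctrb": self.modal_ctrb,
            }
        )


def _check_symmetric(W: np.ndarray, what: str) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"{what} must be a square matrix, got shape {W.shape}")
    if not np.allclose(W, W.T, atol=_SYM_ATOL):
        raise ValueError(f"{what} must be symmetric")
    return W


def stabilize(W: np.ndarray, scheme: str = "largest_singular_value") -> ControlSystem:
    """Rescale a connectome so the implied linear system is stable.

    ``A = W / (1 + sigma_max(W))`` guarantees spectral radius < 1 for any
    symmetric ``W`` (for symmetric matrices sigma_max equals the spectral
    radius, so all eigenvalues shrink strictly inside the unit circle).
    The scheme and factor are recorded so downstream results carry their
    normalization provenance.
    """
    W = _check_symmetric(W, "connectome matrix")
    if scheme != "largest_singular_value":
        raise ValueError(f"unknown stabilization scheme: {scheme!r}")
    if W.size == 0:
        raise ValueError("empty connectome")
    sigma_max = float(np.linalg.norm(W, 2)) if W.shape[0] > 1 else float(abs(W[0, 0]))
    factor = 1.0 + sigma_max
    A = W / factor
    return ControlSystem(
        A=A,
        normalization={"scheme": scheme, "sigma_max": sigma_max, "factor": factor},
    )


def _check_stable(A: np.ndarray) -> np.ndarray:
    rho = float(np.max(np.abs(np.linalg.eigvalsh(A))))
    if rho >= 1.0:
        raise ValueError(f"system matrix is unstable (spectral radius {rho:.6g} >= 1)")
    return A


def average_controllability(system: ControlSystem) -> np.ndarray:
    """Per-region average controllability (trace of the single-input Gramian).

    For input ``b_i = e_i`` the Gramian trace is
    ``trace(W_i) = sum_t e_i' (A')^t A^t e_i = M_ii`` where
    ``M = sum_t (A')^t A^t`` solves the discrete Lyapunov equation
    ``M = A' M A + I``.  One Lyapunov solve therefore yields every
    region's value on the diagonal.  Values are >= 1 because the t = 0
    term alone contributes ``||e_i||^2 = 1``.
    """
    A = _check_symmetric(system.A, "system matrix")
    _check_stable(A)
    M = sla.solve_discrete_lyapunov(A.T, np.eye(A.shape[0]))
    return np.diag(M).copy()


def modal_controllability(system: ControlSystem) -> np.ndarray:
    """Per-region modal controllability ``phi_i = sum_j (1 - lambda_j^2) v_ij^2``.

    Requires a symmetric system matrix: the spectrum is then real and the
    eigenvectors orthonormal, which the formula assumes.  Each ``phi_i``
    lies in ``(1 - rho(A)^2, 1]`` for a stable system, and equals 1
    exactly when A = 0 (every mode maximally transient).
    """
    A = _check_symmetric(system.A, "system matrix")
    _check_stable(A)
    lam, V = np.linalg.eigh(A)
    weights = 1.0 - lam**2
    return (V**2) @ weights


def network_controllability(
    per_roi_values: Sequence[float] | np.ndarray,
    network_assignment: Sequence[str] | Mapping[int, str],
) -> dict:
    """Unweighted mean of a node metric within each network label.

    ``network_assignment`` is either a label per region (parallel to the
    values) or a mapping from region index to label.  Labels with no
    member regions are omitted.  The "unassigned" label is averaged like
    any other; excluding it from modeling is the caller's decision.
    """
    values = np.asarray(per_roi_values, dtype=float)
    if isinstance(network_assignment, Mapping):
        labels = [network_assignment[i] for i in range(len(values))]
    else:
        labels = list(network_assignment)
    if len(labels) != len(values):
        raise ValueError("one network label is required per region")
    ser = pd.Series(values, index=pd.Index(labels, name="network"))
    return ser.groupby(level=0, sort=True).mean().to_dict()


def controllability_profile(
    W: np.ndarray,
    roi_ids: Sequence,
    network_labels: Sequence[str],
) -> ControllabilityProfile:
    """Full controllability profile of one connectome matrix."""
    system = stabilize(W)
    avg = average_controllability(system)
    modal = modal_controllability(system)
    return ControllabilityProfile(
        roi_ids=tuple(roi_ids),
        network_labels=tuple(network_labels),
        avg_ctrb=avg,
        modal_ctrb=modal,
        network_avg=network_controllability(avg, list(network_labels)),
        network_modal=network_controllability(modal, list(network_labels)),
    )
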