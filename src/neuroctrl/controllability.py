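"""Average controllability of a structural connectome.

The connectome is treated as the coupling matrix of a noise-free linear
discrete-time system

    x(t+1) = A x(t) + B u(t),      A = W / (1 + lambda_max(W)),

where W is the FA-weighted adjacency matrix and the normalization by
1 + lambda_max makes A Schur stable (spectral radius lambda_max /
(1 + lambda_max) < 1), so the infinite-horizon controllability Gramian

    W_i = sum_{k>=0} A^k B B' (A')^k,      B = e_i (control at node i)

converges.  Average controllability of node i is trace(W_i): large values
mean input at that node can push the network into many nearby states.

Because A is symmetric, trace(W_i) = sum_k [A^{2k}]_{ii} = [(I - A^2)^{-1}]_{ii},
which the batch routine exploits (one linear solve for all nodes instead of
n Lyapunov solves); the Lyapunov and truncated-series routes are kept as
independent cross-checks.  Every value is >= 1 (the k = 0 term contributes
exactly 1), with equality iff the node is isolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .atlas import SYSTEMS, Parcellation, SystemAssignment
from .connectome import Connectome

logger = logging.getLogger(__name__)

#: Series truncation: tail bound rho^{2(K+1)} / (1 - rho^2) below this value.
SERIES_TAIL_TOL = 1e-10


class ControllabilityError(RuntimeError):
    pass


@dataclass(frozen=True)
class DynamicsMatrix:
    """Schur-stabilized system matrix A = W / (1 + lambda_max(W))."""

    a_norm: np.ndarray
    lambda_max: float

    @property
    def spectral_radius(self) -> float:
        return self.lambda_max / (1.0 + self.lambda_max)


@dataclass(frozen=True)
class ControllabilityProfile:
    subject_id: str
    node_ac: np.ndarray  # (n,) per-node average controllability, each >= 1
    system_ac: dict[str, float]  # one entry per system; NaN if system empty


def stabilize(connectome: Connectome) -> DynamicsMatrix:
    """Normalize the weight matrix into a Schur-stable dynamics matrix."""
    w = connectome.weights
    if w.any():
        lam = float(scipy.linalg.eigvalsh(w, subset_by_index=(w.shape[0] - 1,) * 2)[0])
    else:
        lam = 0.0
    if np.isnan(lam):
        raise ControllabilityError("NaN eigenvalue in stabilization")
    # non-negative symmetric weights have lambda_max >= 0 (Perron root)
    return DynamicsMatrix(w / (1.0 + lam), lam)


def gramian(dynamics: DynamicsMatrix, control_node: int) -> np.ndarray:
    """Infinite-horizon controllability Gramian for single-node input e_i.

    Solves the discrete Lyapunov equation A X A' - X + B B' = 0 directly;
    falls back to the truncated series on solver failure.
    """
    a = dynamics.a_norm
    n = a.shape[0]
    q = np.zeros((n, n))
    q[control_node, control_node] = 1.0
    try:
        w = scipy.linalg.solve_discrete_lyapunov(a, q)
        if np.isnan(w).any():
            raise np.linalg.LinAlgError("NaN in Lyapunov solution")
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.warning(
            "Lyapunov solve failed for node %d (%s); using truncated series",
            control_node,
            exc,
        )
        w = gramian_series(dynamics, control_node)
    return (w + w.T) / 2.0


def _series_horizon(rho: float, tol: float = SERIES_TAIL_TOL) -> int:
    """Smallest K with tail bound rho^{2(K+1)} / (1 - rho^2) < tol."""
    if rho == 0.0:
        return 0
    k = np.log(tol * (1.0 - rho**2)) / (2.0 * np.log(rho)) - 1.0
    return max(0, int(np.ceil(k)))


def gramian_series(
    dynamics: DynamicsMatrix, control_node: int, tol: float = SERIES_TAIL_TOL
) -> np.ndarray:
    """Truncated-series Gramian sum_{k=0}^{K} A^k e_i e_i' (A')^k."""
    a = dynamics.a_norm
    rho = dynamics.spectral_radius
    if rho >= 1.0:
        raise ControllabilityError(f"system not Schur stable (rho = {rho:g})")
    horizon = _series_horizon(rho, tol)
    v = np.zeros(a.shape[0])
    v[control_node] = 1.0
    w = np.zeros_like(a)
    for _ in range(horizon + 1):
        w += np.outer(v, v)
        v = a @ v
    return w


def average_controllability(dynamics: DynamicsMatrix) -> np.ndarray:
    """Per-node average controllability, trace of each single-node Gramian.

    Uses the symmetric-A identity trace(W_i) = [(I - A^2)^{-1}]_{ii}.
    """
    a = dynamics.a_norm
    n = a.shape[0]
    m = np.eye(n) - a @ a
    try:
        ac = np.diag(scipy.linalg.solve(m, np.eye(n), assume_a="pos"))
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - rho<1 keeps m PD
        raise ControllabilityError(f"controllability solve failed: {exc}") from exc
    return np.ascontiguousarray(ac)


def system_controllability(
    node_ac: np.ndarray, assignment: SystemAssignment
) -> dict[str, float]:
    """Unweighted mean of node values per system; NaN for empty systems."""
    out: dict[str, float] = {}
    for s in SYSTEMS:
        members = assignment.members.get(s, ())
        out[s] = float(np.mean(node_ac[list(members)])) if members else float("nan")
    return out


def controllability_profile(
    connectome: Connectome, assignment: SystemAssignment
) -> ControllabilityProfile:
    dyn = stabilize(connectome)
    node_ac = average_controllability(dyn)
    return ControllabilityProfile(
        connectome.subject_id, node_ac, system_controllability(node_ac, assignment)
    )


def controllability_table(
    connectomes,
    parcellation: Parcellation,
    assignment: SystemAssignment,
) -> pd.DataFrame:
    """Per-cohort table: one row per subject, node and system AC columns.

    Columns: subject_id, ac_node_<label> for every node, ac_system_<name>
    for the eight systems.
    """
    rows = []
    for c in connectomes:
        prof = controllability_profile(c, assignment)
        row: dict[str, object] = {"subject_id": prof.subject_id}
        for label, v in zip(parcellation.labels, prof.node_ac):
            row[f"ac_node_{label}"] = v
        for s in SYSTEMS:
            row[f"ac_system_{s}"] = prof.system_ac[s]
        rows.append(row)
    return pd.DataFrame(rows)
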