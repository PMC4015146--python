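"""Label propagation within and between networks.

Within-network diffusion solves

    min_x  sum_jk M_jk (x_j - x_k)^2  +  (1-a)/a * sum_j (x_j - x0_j)^2

whose fixed point is x = (1-a)(I - aM)^{-1} x0, reachable either by direct
solve (``closed_form``) or by iterating x <- aMx + (1-a)x0 (``iterative``)
until the residual drops below kappa.  Because M is degree-normalized its
spectral radius is at most 1, so with a < 1 the iteration contracts
geometrically with ratio a.

Between networks, each destination node receives the unweighted mean of its
cross-network neighbors' values; a survival fraction gamma then zeroes the
lowest ceil(|V|(1-gamma)) values to stop weak, noisy signal from spreading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as splinalg

from .hetnet import DomainNetwork, RelationNetwork, StateVector, ValidationError

__all__ = [
    "PropagationParams",
    "normalize_prior",
    "propagate_within",
    "propagate_between",
    "apply_gamma_threshold",
]


@dataclass(frozen=True)
class PropagationParams:
    """Tunable knobs of the propagation pipeline.

    Parameters
    ----------
    alpha : float in [0, 1]
        Importance of network smoothing relative to the prior; 1-alpha is
        the restart weight pulling values back toward the seeds.
    kappa : float > 0
        Stopping tolerance for the iterative solver (max-norm of the
        residual between successive iterates).
    gamma : float in (0, 1]
        Survival fraction for between-network thresholding: a fraction
        gamma of the destination nodes (the highest-valued ones) keep
        their value, the rest are zeroed.
    max_iters : int
        Safety cap on iterations; reaching it raises instead of returning
        a non-converged state.
    method : {"closed_form", "iterative"}
        Default within-network solver.
    """

    alpha: float = 0.9
    kappa: float = 1e-5
    gamma: float = 0.00375
    max_iters: int = 1000
    method: str = "closed_form"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")
        if not self.kappa > 0:
            raise ValidationError(f"kappa must be > 0, got {self.kappa}")
        if not 0.0 < self.gamma <= 1.0:
            raise ValidationError(f"gamma must be in (0, 1], got {self.gamma}")
        if self.max_iters < 1:
            raise ValidationError(f"max_iters must be >= 1, got {self.max_iters}")
        if self.method not in ("closed_form", "iterative"):
            raise ValidationError(f"unknown propagation method {self.method!r}")


def normalize_prior(state: StateVector) -> StateVector:
    """Scale nonzero values to sum to 1 (the prior information set).

    The support is unchanged; an all-zero state is an error because an
    empty prior set gives the diffusion nothing to spread.
    """
    total = state.values.sum()
    if total == 0:
        raise ValidationError("empty prior set: all state values are zero")
    return StateVector(state.network_id, state.values / total)


def _iterate(M: sparse.csr_matrix, x0: np.ndarray, alpha: float, kappa: float,
             max_iters: int) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Run the diffusion iteration.

    Returns the converged state and the residual history as (max-norm,
    2-norm) pairs per iteration; stopping tests the max-norm against kappa.
    """
    x = x0.copy()
    residuals: list[tuple[float, float]] = []
    for _ in range(max_iters):
        x_next = alpha * (M @ x) + (1.0 - alpha) * x0
        diff = x_next - x
        res_inf = float(np.abs(diff).max())
        residuals.append((res_inf, float(np.linalg.norm(diff))))
        x = x_next
        if res_inf <= kappa:
            return x, residuals
    raise ValidationError(
        f"propagation did not converge within {max_iters} iterations "
        f"(final residual {residuals[-1][0]:.3e} > kappa={kappa:.3e})"
    )


def propagate_within(
    network: DomainNetwork,
    prior: StateVector,
    params: PropagationParams,
    method: str | None = None,
    return_residuals: bool = False,
):
    """Diffuse a prior-normalized state over one domain network.

    Parameters
    ----------
    network : DomainNetwork
    prior : StateVector
        Already prior-normalized (nonzero values summing to 1).
    params : PropagationParams
    method : optional override of ``params.method``.
    return_residuals : bool
        If true, also return the list of successive (max-norm, 2-norm)
        residual pairs (iterative method only; the closed form returns an
        empty list).

    Returns
    -------
    StateVector, or (StateVector, list[float]) when ``return_residuals``.
    """
    if prior.network_id != network.id:
        raise ValidationError(
            f"prior belongs to network {prior.network_id!r}, not {network.id!r}"
        )
    method = method or params.method
    M = network.norm_adjacency
    x0 = prior.values
    alpha = params.alpha
    residuals: list[tuple[float, float]] = []
    if alpha == 0.0:
        x = x0.copy()
    elif method == "closed_form":
        if alpha >= 1.0:
            raise ValidationError(
                "closed-form propagation requires alpha < 1: I - alpha*M is "
                "singular at alpha = 1"
            )
        A = sparse.eye(network.n_nodes, format="csc") - alpha * M
        try:
            x = (1.0 - alpha) * splinalg.spsolve(A, x0)
        except RuntimeError as exc:  # singular factorization
            raise ValidationError(
                f"singular system in closed-form propagation: {exc}; use alpha < 1"
            ) from exc
        x = np.atleast_1d(np.asarray(x, dtype=float))
    else:
        x, residuals = _iterate(M, x0, alpha, params.kappa, params.max_iters)
    # roundoff can leave values a hair below zero; the flow is nonnegative
    x = np.maximum(x, 0.0)
    out = StateVector(network.id, x)
    if return_residuals:
        return out, residuals
    return out


def propagate_between(
    source_state: StateVector,
    relation: RelationNetwork,
    dest: DomainNetwork,
) -> StateVector:
    """Push values across a relation: each destination node takes the
    unweighted mean of its cross-network neighbors; nodes with no
    cross-network neighbor get 0.
    """
    if dest.id not in (relation.source_id, relation.target_id):
        raise ValidationError(
            f"relation {relation.source_id!r}-{relation.target_id!r} does not "
            f"connect to {dest.id!r}"
        )
    if relation.other(dest.id) != source_state.network_id:
        raise ValidationError(
            f"relation {relation.source_id!r}-{relation.target_id!r} does not "
            f"connect {source_state.network_id!r} to {dest.id!r}"
        )
    adj = relation.adjacency_toward(dest.id)
    counts = np.asarray(adj.sum(axis=1)).ravel()
    sums = adj @ source_state.values
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return StateVector(dest.id, values)


def apply_gamma_threshold(state: StateVector, gamma: float) -> StateVector:
    """Zero the ceil(|V|*(1-gamma)) lowest values; keep the rest unchanged.

    Ties are broken by canonical node index: among equal values the lower
    index is zeroed first, so the operation is deterministic.
    """
    if not 0.0 < gamma <= 1.0:
        raise ValidationError(f"gamma must be in (0, 1], got {gamma}")
    values = state.values
    n = values.size
    n_zero = int(np.ceil(n * (1.0 - gamma)))
    if n_zero == 0:
        return state.copy()
    # stable sort on value => equal values ordered by index, low index first
    order = np.argsort(values, kind="stable")
    out = values.copy()
    out[order[:n_zero]] = 0.0
    return StateVector(state.network_id, out)
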