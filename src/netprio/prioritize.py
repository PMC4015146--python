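"""Path enumeration, propagation along paths, and correlation ranking.

The query signal is diffused within the query network, pushed along every
simple path of networks leading to (but not entering) the target network,
and projected onto target nodes through the last relation's normalized
adjacency.  Each candidate target entity is scored by the Pearson
correlation between the concatenated projections and the candidate's own
diffusion profile repeated once per path; candidates whose neighborhood
pattern matches the propagated query evidence rank first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hetnet import DomainNetwork, GlobalGraph, StateVector, ValidationError, init_state
from .propagate import (
    PropagationParams,
    apply_gamma_threshold,
    normalize_prior,
    propagate_between,
    propagate_within,
)

__all__ = [
    "NetworkPath",
    "PathResult",
    "RankedList",
    "enumerate_paths",
    "propagate_along_path",
    "score_correlation",
    "prioritize",
]


@dataclass(frozen=True)
class NetworkPath:
    """An ordered sequence of domain ids from query to target network."""

    sequence: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValidationError("a network path needs at least two networks")
        if len(set(self.sequence)) != len(self.sequence):
            raise ValidationError("network path must not repeat a network")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PathResult:
    """Propagation outcome for one path.

    ``penultimate_state`` holds the diffused values on the last non-target
    network; ``projected`` is that state pushed through the final relation's
    normalized adjacency, one value per target-network node.
    """

    path: NetworkPath
    penultimate_state: StateVector
    projected: np.ndarray


@dataclass
class RankedList:
    """Candidates of the target network ordered by decreasing score.

    ``entries`` are (entity id, score, rank) with ranks 1..|V_t|; ties in
    score are ordered by canonical node index.
    """

    target_id: str
    entries: list[tuple[str, float, int]]

    def rank_of(self, entity: str) -> int:
        for name, _, rank in self.entries:
            if name == entity:
                return rank
        raise ValidationError(f"entity {entity!r} not in ranked list")

    def scores(self) -> dict[str, float]:
        return {name: score for name, score, _ in self.entries}


def enumerate_paths(
    graph: GlobalGraph, query_id: str, target_id: str
) -> list[NetworkPath]:
    """All simple paths from query to target network on the meta-graph.

    Paths visit each network at most once and are returned in lexicographic
    order of their domain-id sequences, so downstream concatenation order is
    deterministic.
    """
    for did in (query_id, target_id):
        if did not in graph.domains:
            raise ValidationError(f"unknown network {did!r}")
    if query_id == target_id:
        raise ValidationError("query and target network must differ")
    meta = graph.meta_graph
    paths: list[NetworkPath] = []
    stack = [query_id]
    on_stack = {query_id}

    def dfs(current: str) -> None:
        if current == target_id:
            paths.append(NetworkPath(tuple(stack)))
            return
        for nxt in sorted(meta.neighbors(current)):
            if nxt in on_stack:
                continue
            stack.append(nxt)
            on_stack.add(nxt)
            dfs(nxt)
            stack.pop()
            on_stack.discard(nxt)

    dfs(query_id)
    if not paths:
        raise ValidationError(
            f"query and target networks are disconnected: no path from "
            f"{query_id!r} to {target_id!r}"
        )
    paths.sort(key=lambda p: p.sequence)
    return paths


def propagate_along_path(
    graph: GlobalGraph,
    path: NetworkPath,
    query_state_hat: StateVector,
    params: PropagationParams,
) -> PathResult:
    """Propagate the diffused query state along one path.

    At each intermediate network the steps are: cross-network mean, gamma
    thresholding, prior normalization over the survivors, within-network
    diffusion.  The target network itself is never entered; the final
    penultimate state is projected onto target nodes through the normalized
    adjacency of the last relation.  A state thresholded to all zeros is
    carried forward as-is (nothing left to diffuse).
    """
    seq = path.sequence
    if query_state_hat.network_id != seq[0]:
        raise ValidationError(
            f"query state lives on {query_state_hat.network_id!r}, path starts "
            f"at {seq[0]!r}"
        )
    state = query_state_hat
    for j in range(len(seq) - 2):
        relation = graph.relation_between(seq[j], seq[j + 1])
        dest = graph.domains[seq[j + 1]]
        state = propagate_between(state, relation, dest)
        state = apply_gamma_threshold(state, params.gamma)
        if state.values.sum() == 0:
            continue  # signal-free: skip diffusion, carry zeros forward
        state = normalize_prior(state)
        state = propagate_within(dest, state, params)
    last_relation = graph.relation_between(seq[-2], seq[-1])
    S_a = last_relation.norm_toward(seq[-1])  # target rows x penultimate cols
    projected = np.asarray(S_a @ state.values, dtype=float)
    return PathResult(path=path, penultimate_state=state, projected=projected)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation with the zero-variance convention score = 0."""
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(np.sqrt((xd * xd).sum()))
    sy = float(np.sqrt((yd * yd).sum()))
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float((xd * yd).sum() / (sx * sy))


def score_correlation(
    path_results: list[PathResult], target_state_hat: StateVector
) -> float:
    """Correlation between query-side projections and the target diffusion.

    The projections of all paths are concatenated into one vector and
    correlated against the target-network diffusion profile repeated once
    per path.  A zero-variance side (e.g. no signal reached the target's
    neighborhood) scores 0: such a candidate carries no evidence.
    """
    if not path_results:
        raise ValidationError("need at least one path result")
    x_bar = np.concatenate([pr.projected for pr in path_results])
    t_bar = np.tile(target_state_hat.values, len(path_results))
    if x_bar.size != t_bar.size:
        raise AssertionError(
            "projection/target length mismatch: "
            f"{x_bar.size} != {t_bar.size}"
        )
    return _pearson(x_bar, t_bar)


def _target_diffusion_matrix(
    target: DomainNetwork, params: PropagationParams
) -> np.ndarray:
    """Columns are the diffusion profiles for every single-node target set.

    For T = {e} the prior is the unit vector at e, so the diffused state is
    column e of (1-alpha)(I - alpha*M_t)^{-1}; factorizing once replaces the
    per-candidate iterative solve with an identical linear map.
    """
    alpha = params.alpha
    n = target.n_nodes
    if alpha == 0.0:
        return np.eye(n)
    if alpha >= 1.0:
        raise ValidationError(
            "closed-form propagation requires alpha < 1: I - alpha*M is "
            "singular at alpha = 1"
        )
    A = np.eye(n) - alpha * target.norm_adjacency.toarray()
    X = (1.0 - alpha) * np.linalg.inv(A)
    return np.maximum(X, 0.0)


def prioritize(
    graph: GlobalGraph,
    query_set: set[str] | list[str],
    query_id: str,
    target_id: str,
    params: PropagationParams | None = None,
) -> RankedList:
    """Rank every target-network entity by correlation with the query set.

    The query diffusion and the per-path projections are computed once (they
    do not depend on the candidate); each candidate e is then scored with
    its own target set T = {e}.

    Returns
    -------
    RankedList
        All |V_t| entities, scores descending, ties by node index.
    """
    params = params or PropagationParams()
    if not query_set:
        raise ValidationError("query set must not be empty")
    query_net = graph.domains[query_id]
    target_net = graph.domains[target_id]

    prior = normalize_prior(init_state(query_net, query_set))
    x_q_hat = propagate_within(query_net, prior, params)

    paths = enumerate_paths(graph, query_id, target_id)
    results = [propagate_along_path(graph, p, x_q_hat, params) for p in paths]
    x_bar = np.concatenate([pr.projected for pr in results])

    X_t = _target_diffusion_matrix(target_net, params)
    n_paths = len(paths)
    scores = np.empty(target_net.n_nodes)
    for e in range(target_net.n_nodes):
        t_bar = np.tile(X_t[:, e], n_paths)
        scores[e] = _pearson(x_bar, t_bar)

    order = np.lexsort((np.arange(scores.size), -scores))
    entries = [
        (target_net.nodes[i], float(scores[i]), rank)
        for rank, i in enumerate(order, start=1)
    ]
    return RankedList(target_id=target_id, entries=entries)
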