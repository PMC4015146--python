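"""Leave-one-out benchmarking: ROC/AUC and normalized mean rank.

Each trial hides one known query-target association (the direct relation
arc), re-runs the full prioritization with the query entity as the query
set, and records where the true target lands in the ranking.  With one
positive among n-1 negatives per trial, the per-trial ROC contribution is
the Mann-Whitney score (n - rank)/(n - 1); averaging over trials gives the
AUC, and averaging the per-trial step curves gives the pooled ROC points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hetnet import GlobalGraph, RelationNetwork, ValidationError
from .prioritize import prioritize
from .propagate import PropagationParams

__all__ = [
    "LooTrial",
    "BenchmarkReport",
    "run_loo",
    "rank_based_auc",
    "normalized_mean_rank",
]


@dataclass
class LooTrial:
    query_entity: str
    true_target: str
    removed_edges: list[tuple[str, str]]
    rank: int
    n_candidates: int


@dataclass
class BenchmarkReport:
    trials: list[LooTrial]
    auc: float
    roc_points: list[tuple[float, float]]
    normalized_mean_rank: float
    rank_std: float
    n_candidates: int = field(default=0)

    def summary(self) -> str:
        return (
            f"trials: {len(self.trials)}\n"
            f"candidates per trial: {self.n_candidates}\n"
            f"AUC: {self.auc:.6f}\n"
            f"normalized mean rank: {self.normalized_mean_rank:.6f} "
            f"(std {self.rank_std:.6f})"
        )


def rank_based_auc(
    ranks: list[int], n_candidates: int
) -> tuple[float, list[tuple[float, float]]]:
    """AUC and pooled ROC points from per-trial ranks.

    One positive per trial: the trial's score is (n - rank)/(n - 1).  ROC
    points are built on the cutoff grid r = 0..n with TPR(r) the fraction of
    trials whose true target is ranked within the top r, and FPR(r) the mean
    fraction of negatives admitted at that cutoff.
    """
    if n_candidates < 2:
        raise ValidationError("need at least 2 candidates for a ROC")
    arr = np.asarray(ranks, dtype=float)
    if arr.size == 0:
        raise ValidationError("no trials: empty rank list")
    if arr.min() < 1 or arr.max() > n_candidates:
        raise ValidationError("ranks must lie in [1, n_candidates]")
    n = n_candidates
    auc = float(((n - arr) / (n - 1)).mean())
    points: list[tuple[float, float]] = []
    for r in range(n + 1):
        hit = arr <= r
        tpr = float(hit.mean())
        fpr = float(((r - hit.astype(float)) / (n - 1)).mean())
        points.append((fpr, tpr))
    return auc, points


def normalized_mean_rank(
    ranks: list[int], n_candidates: int
) -> tuple[float, float]:
    """Mean and standard deviation of ranks scaled by the candidate count."""
    arr = np.asarray(ranks, dtype=float)
    if arr.size == 0:
        raise ValidationError("no trials: empty rank list")
    if arr.min() < 1 or arr.max() > n_candidates:
        raise ValidationError("ranks must lie in [1, n_candidates]")
    scaled = arr / n_candidates
    return float(scaled.mean()), float(scaled.std())


def _drop_arc(rel: RelationNetwork, u: str, v: str) -> RelationNetwork:
    """Relation with the (u, v) arc removed and normalization recomputed."""
    src_idx = {name: i for i, name in enumerate(rel.source_nodes)}
    dst_idx = {name: i for i, name in enumerate(rel.target_nodes)}
    if u in src_idx and v in dst_idx:
        i, j = src_idx[u], dst_idx[v]
    elif v in src_idx and u in dst_idx:
        i, j = src_idx[v], dst_idx[u]
    else:
        raise ValidationError(
            f"pair ({u!r}, {v!r}) does not span relation "
            f"{rel.source_id!r}-{rel.target_id!r}"
        )
    weights = rel.weights.tolil(copy=True)
    weights[i, j] = 0.0
    return RelationNetwork(
        source_id=rel.source_id,
        target_id=rel.target_id,
        source_nodes=rel.source_nodes,
        target_nodes=rel.target_nodes,
        weights=weights.tocsr(),
    )


def run_loo(
    graph: GlobalGraph,
    relation_pairs: list[tuple[str, str]],
    params: PropagationParams | None = None,
    remove_arcs: bool = True,
) -> BenchmarkReport:
    """Leave-one-out benchmark over known query-target associations.

    For each (query_entity, true_target) pair the direct relation arc is
    removed (both orientations), the relation matrix renormalized, the
    prioritization run with the query entity as the query set, and the rank
    of the true target recorded; the arc is restored before the next trial.

    With ``remove_arcs=False`` the pairs are scored against the graph as-is
    — the mode for evaluating associations that are absent from the graph
    by construction (e.g. newly curated or label-shuffled pairs).
    """
    params = params or PropagationParams()
    if not relation_pairs:
        raise ValidationError("no trials: empty pair list")

    resolved = []
    for q_ent, t_ent in relation_pairs:
        q_id = graph.owner_of(q_ent)
        t_id = graph.owner_of(t_ent)
        if q_id == t_id:
            raise ValidationError(
                f"pair ({q_ent!r}, {t_ent!r}): both entities in network {q_id!r}"
            )
        rel = graph.relation_between(q_id, t_id)
        if remove_arcs:
            # validate every pair is an existing arc before any trial runs
            adj = rel.adjacency_sets(t_id)
            t_pos = graph.domains[t_id].index[t_ent]
            if q_ent not in adj[t_pos]:
                raise ValidationError(
                    f"pair ({q_ent!r}, {t_ent!r}) is not an existing arc of "
                    f"relation {q_id!r}-{t_id!r}"
                )
        resolved.append((q_ent, t_ent, q_id, t_id, rel))

    trials: list[LooTrial] = []
    n_cand = None
    for q_ent, t_ent, q_id, t_id, rel in resolved:
        removed = []
        if remove_arcs:
            pruned = _drop_arc(rel, q_ent, t_ent)
            original = graph.replace_relation(pruned)
            removed = [(q_ent, t_ent)]
        try:
            ranking = prioritize(graph, {q_ent}, q_id, t_id, params)
        finally:
            if remove_arcs:
                graph.replace_relation(original)
        rank = ranking.rank_of(t_ent)
        n_cand = graph.domains[t_id].n_nodes
        trials.append(
            LooTrial(
                query_entity=q_ent,
                true_target=t_ent,
                removed_edges=removed,
                rank=rank,
                n_candidates=n_cand,
            )
        )

    ranks = [t.rank for t in trials]
    auc, roc_points = rank_based_auc(ranks, n_cand)
    nmr, std = normalized_mean_rank(ranks, n_cand)
    return BenchmarkReport(
        trials=trials,
        auc=auc,
        roc_points=roc_points,
        normalized_mean_rank=nmr,
        rank_std=std,
        n_candidates=n_cand,
    )
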