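"""File formats and run configuration.

Networks are exchanged as TSV edge lists: two node-id columns and one float
weight column, undirected with each pair listed once, ``#`` comment lines
ignored, header optional.  Relation files use the same format with the two
endpoints belonging to different networks.  The run configuration is YAML.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .hetnet import DomainNetwork, GlobalGraph, RelationNetwork, ValidationError, build_global_graph
from .prioritize import RankedList
from .propagate import PropagationParams

__all__ = [
    "RunConfig",
    "load_config",
    "read_edge_tsv",
    "load_global_graph",
    "write_domain_tsv",
    "write_relation_tsv",
    "write_ranking_tsv",
    "read_pairs_tsv",
    "write_report",
]

# 17 significant digits: doubles survive the write/read round trip exactly
_FLOAT_FMT = "%.17g"


def read_edge_tsv(path: str) -> list[tuple[str, str, float]]:
    """Read (node, node, weight) triples; '#' lines and a header are skipped."""
    if not os.path.exists(path):
        raise ValidationError(f"network file not found: {path}")
    edges: list[tuple[str, str, float]] = []
    first_row = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected 3 tab-separated columns"
                )
            try:
                w = float(parts[2])
            except ValueError:
                if first_row:
                    first_row = False
                    continue  # optional header row
                raise ValidationError(
                    f"{path}:{lineno}: weight {parts[2]!r} is not a number"
                ) from None
            first_row = False
            edges.append((parts[0], parts[1], w))
    return edges


def _nodes_from_edges(edges: list[tuple[str, str, float]]) -> list[str]:
    seen: dict[str, None] = {}
    for u, v, _ in edges:
        seen.setdefault(u)
        seen.setdefault(v)
    return list(seen)


def load_global_graph(
    network_files: dict[str, str],
    relation_files: list[tuple[str, str, str]],
    node_files: dict[str, str] | None = None,
) -> GlobalGraph:
    """Load a global graph from edge-list TSVs.

    ``node_files`` optionally maps a network id to a one-id-per-line
    vocabulary file fixing the canonical node order; otherwise the order of
    first appearance in the edge list is used.
    """
    domain_specs = []
    for did, path in network_files.items():
        edges = read_edge_tsv(path)
        if node_files and did in node_files:
            with open(node_files[did]) as fh:
                nodes = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        else:
            nodes = _nodes_from_edges(edges)
        domain_specs.append((did, nodes, edges))
    relation_specs = [
        (a, b, read_edge_tsv(path)) for a, b, path in relation_files
    ]
    return build_global_graph(domain_specs, relation_specs)


def write_domain_tsv(network: DomainNetwork, path: str) -> None:
    coo = sparse_upper(network)
    with open(path, "w") as fh:
        fh.write("# undirected edge list: node_a\tnode_b\tweight\n")
        for i, j, w in coo:
            fh.write(
                f"{network.nodes[i]}\t{network.nodes[j]}\t{_FLOAT_FMT % w}\n"
            )


def sparse_upper(network: DomainNetwork):
    coo = network.weights.tocoo()
    triples = [
        (int(i), int(j), float(w))
        for i, j, w in zip(coo.row, coo.col, coo.data)
        if i <= j
    ]
    triples.sort()
    return triples


def write_relation_tsv(rel: RelationNetwork, path: str) -> None:
    coo = rel.weights.tocoo()
    triples = sorted(
        (int(i), int(j), float(w)) for i, j, w in zip(coo.row, coo.col, coo.data)
    )
    with open(path, "w") as fh:
        fh.write("# bipartite edge list: source_node\ttarget_node\tweight\n")
        for i, j, w in triples:
            fh.write(
                f"{rel.source_nodes[i]}\t{rel.target_nodes[j]}\t{_FLOAT_FMT % w}\n"
            )


def write_ranking_tsv(ranking: RankedList, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tentity_id\tscore\n")
        for name, score, rank in ranking.entries:
            fh.write(f"{rank}\t{name}\t{score:.6e}\n")


def read_pairs_tsv(path: str) -> list[tuple[str, str]]:
    if not os.path.exists(path):
        raise ValidationError(f"pairs file not found: {path}")
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"{path}: pairs need 2 columns")
            if parts[0] in ("query_entity", "query"):
                continue
            pairs.append((parts[0], parts[1]))
    return pairs


def write_report(report, trial_path: str, summary_path: str) -> None:
    with open(trial_path, "w") as fh:
        fh.write("query_entity\ttrue_target\trank\tn_candidates\n")
        for t in report.trials:
            fh.write(
                f"{t.query_entity}\t{t.true_target}\t{t.rank}\t{t.n_candidates}\n"
            )
    with open(summary_path, "w") as fh:
        fh.write(report.summary() + "\n")


@dataclass
class RunConfig:
    """Validated run configuration for CLI commands."""

    networks: dict[str, str]
    relations: list[tuple[str, str, str]]
    query_network: str
    target_network: str
    query_set: list[str]
    node_files: dict[str, str] | None = None
    params: PropagationParams = field(default_factory=PropagationParams)
    output: str = "ranking.tsv"
    log_level: str = "INFO"

    def load_graph(self) -> GlobalGraph:
        return load_global_graph(self.networks, self.relations, self.node_files)


_KNOWN_KEYS = {
    "networks",
    "node_files",
    "relations",
    "query_network",
    "target_network",
    "query_set",
    "query_set_file",
    "params",
    "output",
    "log_level",
}
_KNOWN_PARAM_KEYS = {"alpha", "kappa", "gamma", "max_iters", "method"}


def load_config(path: str) -> RunConfig:
    """Parse and validate a YAML run configuration, applying defaults."""
    if not os.path.exists(path):
        raise ValidationError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path} is not a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("networks", "query_network", "target_network"):
        if key not in raw:
            raise ValidationError(f"config missing required key {key!r}")

    networks = dict(raw["networks"])
    node_files = dict(raw.get("node_files") or {})
    relations = []
    for item in raw.get("relations", []):
        relations.append((item["a"], item["b"], item["file"]))
    for p in (list(networks.values()) + [f for _, _, f in relations]
              + list(node_files.values())):
        if not os.path.exists(p):
            raise ValidationError(f"referenced file not found: {p}")

    for key in ("query_network", "target_network"):
        if raw[key] not in networks:
            raise ValidationError(
                f"{key} {raw[key]!r} is not among declared networks"
            )

    if "query_set_file" in raw:
        with open(raw["query_set_file"]) as fh:
            query_set = [ln.strip() for ln in fh if ln.strip()]
    else:
        query_set = [str(q) for q in raw.get("query_set", [])]

    praw = dict(raw.get("params", {}))
    unknown = set(praw) - _KNOWN_PARAM_KEYS
    if unknown:
        raise ValidationError(f"unknown parameter keys: {sorted(unknown)}")
    if float(praw.get("alpha", 0.9)) >= 1.0:
        raise ValidationError(
            "alpha must be < 1: the closed-form solve (I - alpha*M)^-1 is "
            "singular at alpha = 1"
        )
    try:
        params = PropagationParams(
            alpha=float(praw.get("alpha", 0.9)),
            kappa=float(praw.get("kappa", 1e-5)),
            gamma=float(praw.get("gamma", 0.00375)),
            max_iters=int(praw.get("max_iters", 1000)),
            method=str(praw.get("method", "closed_form")),
        )
    except ValidationError as exc:
        raise ValidationError(f"invalid params in {path}: {exc}") from exc

    return RunConfig(
        networks=networks,
        relations=relations,
        node_files=node_files or None,
        query_network=raw["query_network"],
        target_network=raw["target_network"],
        query_set=query_set,
        params=params,
        output=str(raw.get("output", "ranking.tsv")),
        log_level=str(raw.get("log_level", "INFO")),
    )
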