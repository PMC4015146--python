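"""Heterogeneous network-of-networks data model.

A global graph couples several *domain networks* (weighted undirected graphs
over one kind of biological entity: genes, diseases, protein domains, ...)
through bipartite *relation networks* that link entities of two different
domains.  Every adjacency matrix is degree-normalized as

    norm(N)_jk = N_jk / sqrt(rowsum_j * colsum_k)

which for a symmetric intra-domain matrix is the symmetric normalization
D^{-1/2} N D^{-1/2} used by flow-propagation methods; it bounds the spectral
radius by 1 and hence guarantees convergence of the label diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import sparse

__all__ = [
    "DomainNetwork",
    "RelationNetwork",
    "GlobalGraph",
    "StateVector",
    "normalize_adjacency",
    "build_global_graph",
    "init_state",
]


class ValidationError(ValueError):
    """Raised when input data violates a structural invariant."""


def _as_csr(raw) -> sparse.csr_matrix:
    if sparse.issparse(raw):
        return raw.tocsr().astype(float)
    return sparse.csr_matrix(np.asarray(raw, dtype=float))


def normalize_adjacency(raw) -> sparse.csr_matrix:
    """Degree-normalize a nonnegative weight matrix.

    Each entry is divided by the square root of the product of its row and
    column sums.  Rows or columns with zero sum (isolated nodes) map to
    all-zero rows/columns: an isolated node neither emits nor receives flow.

    Parameters
    ----------
    raw : array-like or sparse matrix, shape (r, c)
        Nonnegative, finite weights.  Square symmetric for intra-domain
        networks, rectangular for bipartite relations.

    Returns
    -------
    scipy.sparse.csr_matrix
        The normalized matrix, same shape and sparsity pattern.
    """
    mat = _as_csr(raw)
    if mat.nnz:
        data = mat.data
        bad = ~np.isfinite(data)
        if bad.any() or (data < 0).any():
            idx = np.argwhere(~(np.isfinite(mat.toarray()) & (mat.toarray() >= 0)))
            j, k = idx[0]
            raise ValidationError(
                f"adjacency entry at row {j}, column {k} is negative or non-finite"
            )
    row_sums = np.asarray(mat.sum(axis=1)).ravel()
    col_sums = np.asarray(mat.sum(axis=0)).ravel()
    with np.errstate(divide="ignore"):
        r_scale = np.where(row_sums > 0, 1.0 / np.sqrt(row_sums), 0.0)
        c_scale = np.where(col_sums > 0, 1.0 / np.sqrt(col_sums), 0.0)
    out = sparse.diags(r_scale) @ mat @ sparse.diags(c_scale)
    return out.tocsr()


@dataclass
class DomainNetwork:
    """One intra-domain weighted undirected network.

    Attributes
    ----------
    id : str
        Unique network name within the global graph.
    nodes : list of str
        Canonical node order; fixed at construction and used as the index
        for every vector and matrix aligned to this network.
    weights : scipy.sparse.csr_matrix
        Raw symmetric nonnegative edge weights.
    norm_adjacency : scipy.sparse.csr_matrix
        Degree-normalized weights (see :func:`normalize_adjacency`).
    """

    id: str
    nodes: list[str]
    weights: sparse.csr_matrix
    norm_adjacency: sparse.csr_matrix = field(init=False)
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.nodes = list(self.nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError(f"duplicate node id within network {self.id!r}")
        self.weights = _as_csr(self.weights)
        n = len(self.nodes)
        if self.weights.shape != (n, n):
            raise ValidationError(
                f"network {self.id!r}: weight matrix shape {self.weights.shape} "
                f"does not match {n} nodes"
            )
        self.weights.eliminate_zeros()
        diff = abs(self.weights - self.weights.T)
        if diff.nnz and diff.max() > 1e-12:
            raise ValidationError(f"network {self.id!r}: weights not symmetric")
        self.norm_adjacency = normalize_adjacency(self.weights)
        self.index = {v: i for i, v in enumerate(self.nodes)}

    @classmethod
    def from_edges(
        cls, id: str, nodes: Sequence[str], edges: Iterable[tuple[str, str, float]]
    ) -> "DomainNetwork":
        """Build from an undirected edge list (each pair listed once)."""
        order = {v: i for i, v in enumerate(nodes)}
        rows, cols, vals = [], [], []
        for u, v, w in edges:
            for name in (u, v):
                if name not in order:
                    raise ValidationError(
                        f"network {id!r}: edge references unknown node {name!r}"
                    )
            i, j = order[u], order[v]
            rows.append(i), cols.append(j), vals.append(float(w))
            if i != j:
                rows.append(j), cols.append(i), vals.append(float(w))
        mat = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(nodes), len(nodes))
        )
        mat.sum_duplicates()
        return cls(id=id, nodes=list(nodes), weights=mat)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class RelationNetwork:
    """Bipartite relation network linking two domain networks.

    Weights are stored with rows indexed by ``source_id``'s nodes and columns
    by ``target_id``'s nodes; both orientations of the normalized matrix and
    of the unweighted adjacency are exposed through :meth:`norm_toward` and
    :meth:`adjacency_toward` so the matrix oriented toward either endpoint is
    unambiguous.
    """

    source_id: str
    target_id: str
    source_nodes: list[str]
    target_nodes: list[str]
    weights: sparse.csr_matrix  # rows = source nodes, cols = target nodes

    def __post_init__(self) -> None:
        if self.source_id == self.target_id:
            raise ValidationError(
                f"relation endpoints must differ (got {self.source_id!r} twice)"
            )
        self.weights = _as_csr(self.weights)
        shape = (len(self.source_nodes), len(self.target_nodes))
        if self.weights.shape != shape:
            raise ValidationError(
                f"relation {self.source_id!r}-{self.target_id!r}: weight shape "
                f"{self.weights.shape} != {shape}"
            )
        self.weights.eliminate_zeros()
        if self.weights.nnz and self.weights.data.min() < 0:
            raise ValidationError(
                f"relation {self.source_id!r}-{self.target_id!r}: negative weight"
            )
        self._norm = normalize_adjacency(self.weights)

    def endpoints(self) -> frozenset[str]:
        return frozenset((self.source_id, self.target_id))

    def other(self, domain_id: str) -> str:
        if domain_id == self.source_id:
            return self.target_id
        if domain_id == self.target_id:
            return self.source_id
        raise ValidationError(
            f"relation {self.source_id!r}-{self.target_id!r} does not touch "
            f"{domain_id!r}"
        )

    def norm_toward(self, dest_id: str) -> sparse.csr_matrix:
        """Normalized adjacency with rows indexed by ``dest_id``'s nodes."""
        if dest_id == self.target_id:
            return self._norm.T.tocsr()
        if dest_id == self.source_id:
            return self._norm
        raise ValidationError(f"{dest_id!r} is not an endpoint of this relation")

    def adjacency_toward(self, dest_id: str) -> sparse.csr_matrix:
        """Unweighted 0/1 adjacency with rows indexed by ``dest_id``'s nodes."""
        pattern = self.weights.copy()
        pattern.data = np.ones_like(pattern.data)
        if dest_id == self.target_id:
            return pattern.T.tocsr()
        if dest_id == self.source_id:
            return pattern.tocsr()
        raise ValidationError(f"{dest_id!r} is not an endpoint of this relation")

    def adjacency_sets(self, dest_id: str) -> list[set[str]]:
        """Cross-network neighbor sets for every node of ``dest_id``."""
        adj = self.adjacency_toward(dest_id)
        src_nodes = (
            self.source_nodes if dest_id == self.target_id else self.target_nodes
        )
        return [
            {src_nodes[j] for j in adj.indices[adj.indptr[i] : adj.indptr[i + 1]]}
            for i in range(adj.shape[0])
        ]


@dataclass
class GlobalGraph:
    """The heterogeneous global graph: domain networks plus relations.

    ``meta_graph`` is the undirected graph whose vertices are domain ids and
    whose edges mirror the relation networks; propagation paths are
    enumerated on it.
    """

    domains: dict[str, DomainNetwork]
    relations: list[RelationNetwork]
    meta_graph: nx.Graph = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen_pairs: set[frozenset[str]] = set()
        vocab: dict[str, str] = {}
        for dom in self.domains.values():
            for v in dom.nodes:
                if v in vocab:
                    raise ValidationError(
                        f"node id {v!r} appears in both networks "
                        f"{vocab[v]!r} and {dom.id!r}"
                    )
                vocab[v] = dom.id
        for rel in self.relations:
            for did in (rel.source_id, rel.target_id):
                if did not in self.domains:
                    raise ValidationError(
                        f"relation references unknown network {did!r}"
                    )
            pair = rel.endpoints()
            if pair in seen_pairs:
                raise ValidationError(
                    f"duplicate relation between {rel.source_id!r} and "
                    f"{rel.target_id!r}"
                )
            seen_pairs.add(pair)
        self._by_pair = {rel.endpoints(): rel for rel in self.relations}
        self._owner = vocab
        g = nx.Graph()
        g.add_nodes_from(self.domains)
        g.add_edges_from((rel.source_id, rel.target_id) for rel in self.relations)
        self.meta_graph = g

    def relation_between(self, id_a: str, id_b: str) -> RelationNetwork:
        try:
            return self._by_pair[frozenset((id_a, id_b))]
        except KeyError:
            raise ValidationError(
                f"no relation network between {id_a!r} and {id_b!r}"
            ) from None

    def owner_of(self, node_id: str) -> str:
        """Return the id of the domain network containing ``node_id``."""
        try:
            return self._owner[node_id]
        except KeyError:
            raise ValidationError(f"unknown node id {node_id!r}") from None

    def replace_relation(self, new_rel: RelationNetwork) -> RelationNetwork:
        """Swap in a relation for the same domain pair; return the old one."""
        pair = new_rel.endpoints()
        old = self._by_pair[pair]
        self.relations[self.relations.index(old)] = new_rel
        self._by_pair[pair] = new_rel
        return old


@dataclass
class StateVector:
    """Per-node label values on one domain network, in canonical node order."""

    network_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("state values must be a 1-D vector")

    def copy(self) -> "StateVector":
        return StateVector(self.network_id, self.values.copy())


def build_global_graph(
    domain_specs: Sequence[tuple[str, Sequence[str], Iterable[tuple[str, str, float]]]],
    relation_specs: Sequence[tuple[str, str, Iterable[tuple[str, str, float]]]],
) -> GlobalGraph:
    """Assemble a validated :class:`GlobalGraph` from edge-list specs.

    Parameters
    ----------
    domain_specs : sequence of (id, nodes, edges)
        One entry per domain network; ``edges`` are (u, v, weight) triples
        with both endpoints in ``nodes``.
    relation_specs : sequence of (id_a, id_b, edges)
        One entry per relation; edge endpoints may be listed in either order
        but must belong one to each named network.

    All normalized matrices are computed eagerly so downstream propagation
    never touches raw weights.
    """
    domains: dict[str, DomainNetwork] = {}
    for did, nodes, edges in domain_specs:
        if did in domains:
            raise ValidationError(f"duplicate network id {did!r}")
        domains[did] = DomainNetwork.from_edges(did, nodes, edges)

    relations = []
    for id_a, id_b, edges in relation_specs:
        for did in (id_a, id_b):
            if did not in domains:
                raise ValidationError(f"relation references unknown network {did!r}")
        src, dst = domains[id_a], domains[id_b]
        rows, cols, vals = [], [], []
        for u, v, w in edges:
            if u in src.index and v in dst.index:
                i, j = src.index[u], dst.index[v]
            elif v in src.index and u in dst.index:
                i, j = src.index[v], dst.index[u]
            else:
                missing = u if u not in src.index and u not in dst.index else v
                raise ValidationError(
                    f"relation {id_a!r}-{id_b!r}: edge references unknown node "
                    f"{missing!r}"
                )
            rows.append(i), cols.append(j), vals.append(float(w))
        mat = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(src.n_nodes, dst.n_nodes)
        )
        mat.sum_duplicates()
        relations.append(
            RelationNetwork(
                source_id=id_a,
                target_id=id_b,
                source_nodes=src.nodes,
                target_nodes=dst.nodes,
                weights=mat,
            )
        )
    return GlobalGraph(domains=domains, relations=relations)


def init_state(network: DomainNetwork, seed_set: Iterable[str]) -> StateVector:
    """Indicator state: 1 on every seed node, 0 elsewhere."""
    values = np.zeros(network.n_nodes)
    for node in seed_set:
        if node not in network.index:
            raise ValidationError(
                f"node {node!r} is not in network {network.id!r}"
            )
        values[network.index[node]] = 1.0
    return StateVector(network.id, values)
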