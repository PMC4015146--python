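import numpy as np
import pytest
from scipy import sparse

from netprio import DomainNetwork, build_global_graph


def random_symmetric_network(rng, n, density=0.3, net_id="net", prefix="v"):
    """Random weighted undirected DomainNetwork with U(0,1] weights."""
    mask = rng.random((n, n)) < density
    w = 1.0 - rng.random((n, n))
    upper = np.triu(mask * w, k=1)
    mat = upper + upper.T
    nodes = [f"{prefix}{i}" for i in range(n)]
    return DomainNetwork(id=net_id, nodes=nodes, weights=sparse.csr_matrix(mat))


def tiny_triangle_graph():
    """Hand-sized 3-domain graph: query q, intermediate m, target t.

    Meta-graph is the triangle q-m-t, so two paths [q,t] and [q,m,t]
    connect query to target.  Node counts 4/3/4.
    """
    domain_specs = [
        ("q", ["q0", "q1", "q2", "q3"],
         [("q0", "q1", 1.0), ("q1", "q2", 0.5), ("q2", "q3", 0.8)]),
        ("m", ["m0", "m1", "m2"], [("m0", "m1", 1.0), ("m1", "m2", 0.4)]),
        ("t", ["t0", "t1", "t2", "t3"],
         [("t0", "t1", 0.6), ("t2", "t3", 0.9)]),
    ]
    relation_specs = [
        ("q", "m", [("q0", "m0", 1.0), ("q1", "m1", 0.7)]),
        ("m", "t", [("m0", "t0", 1.0), ("m2", "t2", 0.5)]),
        ("q", "t", [("q0", "t0", 1.0), ("q3", "t3", 0.3)]),
    ]
    return build_global_graph(domain_specs, relation_specs)


@pytest.fixture
def triangle_graph():
    return tiny_triangle_graph()


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
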