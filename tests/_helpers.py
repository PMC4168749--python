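import numpy as np

from funcnet import NetworkMeta, network_from_edges


def make_net(n, edges, name="net", group="g", **meta_kw):
    """Shorthand: a SparseNetwork over n genes from (i, j, w) triples."""
    return network_from_edges(n, edges, NetworkMeta(name=name, group=group, **meta_kw))


def dense_propagation_oracle(w_dense, y, lam):
    """Direct dense solve of (I + lam*(D - W)) f = y for small instances."""
    w = np.asarray(w_dense, dtype=float)
    d = np.diag(w.sum(axis=1))
    a = np.eye(len(y)) + lam * (d - w)
    return np.linalg.solve(a, np.asarray(y, dtype=float))
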