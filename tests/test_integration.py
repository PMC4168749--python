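"""Network weighting, composite construction, provenance and display collapse."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.optimize import nnls

from funcnet import (
    NetworkWeights,
    collapse_for_display,
    combine,
    normalize_symmetric,
    weight_by_group,
    weight_equal,
    weight_query_adaptive,
)
from _helpers import make_net


class TestBaselineWeights:
    def test_equal_split(self):
        nets = [make_net(4, [(0, 1, 1.0)], name=f"n{i}") for i in range(4)]
        w = weight_equal(nets)
        assert all(v == pytest.approx(0.25) for v in w.weights.values())

    def test_single_network_gets_one(self):
        w = weight_equal([make_net(3, [(0, 1, 1.0)])])
        assert list(w.weights.values()) == [1.0]

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            weight_equal([])
        with pytest.raises(ValueError):
            weight_by_group([])

    def test_group_split(self):
        nets = [
            make_net(4, [(0, 1, 1.0)], name="c1", group="coexp"),
            make_net(4, [(0, 1, 1.0)], name="c2", group="coexp"),
            make_net(4, [(0, 1, 1.0)], name="p1", group="ppi"),
        ]
        w = weight_by_group(nets)
        assert w.weights["c1"] == pytest.approx(0.25)
        assert w.weights["c2"] == pytest.approx(0.25)
        assert w.weights["p1"] == pytest.approx(0.5)

    def test_single_group_equals_equal_weighting(self):
        nets = [make_net(4, [(0, 1, 1.0)], name=f"n{i}", group="same") for i in range(3)]
        assert weight_by_group(nets).weights == pytest.approx(weight_equal(nets).weights)

    def test_three_singleton_groups(self):
        nets = [make_net(4, [(0, 1, 1.0)], name=f"n{i}", group=f"g{i}") for i in range(3)]
        assert all(v == pytest.approx(1 / 3) for v in weight_by_group(nets).weights.values())


def nnls_oracle(networks, query, n, ridge=1e-3):
    """Independent NNLS solution on the explicitly enumerated pair design."""
    q = sorted(query)
    others = [i for i in range(n) if i not in set(q)]
    pairs, t = [], []
    for a in range(len(q)):
        for b in range(a + 1, len(q)):
            pairs.append((q[a], q[b]))
            t.append(1.0)
    for a in q:
        for b in others:
            pairs.append((a, b))
            t.append(0.0)
    mats = [normalize_symmetric(net).adjacency.toarray() for net in networks]
    X = np.array([[m[i, j] for m in mats] for i, j in pairs])
    m = len(networks)
    ones = np.ones((len(pairs), 1))
    A = np.hstack([X, ones, -ones])
    A = np.vstack([A, np.hstack([np.sqrt(ridge) * np.eye(m), np.zeros((m, 2))])])
    b = np.concatenate([t, np.zeros(m)])
    sol, _ = nnls(A, b)
    c = sol[:m]
    return c / c.sum() if c.sum() > 0 else c


class TestQueryAdaptiveWeights:
    def test_query_covering_network_beats_disjoint_network(self):
        n, query = 6, [0, 1, 2]
        informative = make_net(
            n, [(0, 1, 1.0), (0, 2, 1.0), (1, 2, 1.0)], name="informative"
        )
        disjoint = make_net(n, [(3, 4, 1.0), (4, 5, 1.0)], name="disjoint")
        w = weight_query_adaptive([informative, disjoint], query)
        assert w.weights["informative"] > w.weights["disjoint"]
        oracle = nnls_oracle([informative, disjoint], query, n)
        assert w.weights["informative"] == pytest.approx(oracle[0], abs=1e-8)
        assert w.weights["disjoint"] == pytest.approx(oracle[1], abs=1e-8)

    def test_uninformative_networks_fall_back_to_equal(self):
        n, query = 6, [0, 1]
        # edges exist but none touches any pair involving a query gene
        a = make_net(n, [(3, 4, 1.0)], name="a")
        b = make_net(n, [(4, 5, 1.0)], name="b")
        with pytest.warns(UserWarning, match="equal"):
            w = weight_query_adaptive([a, b], query)
        assert w.method == "equal"
        assert all(v == pytest.approx(0.5) for v in w.weights.values())

    def test_duplicated_network_splits_single_copy_weight(self):
        n, query = 6, [0, 1, 2]
        edges = [(0, 1, 1.0), (1, 2, 1.0), (3, 4, 0.5)]
        twin1 = make_net(n, edges, name="twin1")
        twin2 = make_net(n, edges, name="twin2")
        single = make_net(n, edges, name="single")
        noise = make_net(n, [(0, 3, 1.0), (4, 5, 1.0)], name="noise")
        w_two = weight_query_adaptive([twin1, twin2, noise], query)
        w_one = weight_query_adaptive([single, noise], query)
        # ridge symmetry forces a near-equal split; the pair shares the
        # weight structure the single copy would get
        assert w_two.weights["twin1"] == pytest.approx(w_two.weights["twin2"], abs=1e-6)
        assert w_two.weights["twin1"] + w_two.weights["twin2"] == pytest.approx(
            w_one.weights["single"], rel=0.05
        )

    def test_single_gene_query_is_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            weight_query_adaptive([make_net(4, [(0, 1, 1.0)])], [0])

    def test_invariant_to_network_order(self):
        n, query = 8, [0, 1, 2, 3]
        rng = np.random.default_rng(7)
        nets = []
        for k in range(3):
            iu, ju = np.triu_indices(n, k=1)
            keep = rng.random(iu.size) < 0.4
            nets.append(
                make_net(
                    n,
                    [(int(i), int(j), float(rng.uniform(0.2, 1)))
                     for i, j in zip(iu[keep], ju[keep])],
                    name=f"net{k}",
                )
            )
        w_fwd = weight_query_adaptive(nets, query)
        w_rev = weight_query_adaptive(list(reversed(nets)), query)
        for name in w_fwd.weights:
            assert w_fwd.weights[name] == pytest.approx(w_rev.weights[name], abs=1e-8)


class TestCombine:
    def test_shared_pair_sums(self):
        a = make_net(2, [(0, 1, 0.3)], name="a")
        b = make_net(2, [(0, 1, 0.5)], name="b")
        # single-edge networks normalize to weight 1; use alpha to carry 0.3/0.5
        w = NetworkWeights({"a": 0.3, "b": 0.5}, "equal")
        comp = combine([a, b], w)
        assert comp.adjacency[0, 1] == pytest.approx(0.8)
        assert len(comp.provenance[(0, 1)]) == 2

    def test_zero_alpha_network_absent_from_provenance(self):
        a = make_net(3, [(0, 1, 1.0)], name="a")
        b = make_net(3, [(1, 2, 1.0)], name="b")
        comp = combine([a, b], NetworkWeights({"a": 0.0, "b": 1.0}, "equal"))
        norm_b = normalize_symmetric(b).adjacency
        assert np.allclose(comp.adjacency.toarray(), norm_b.toarray())
        assert all(
            rec.network == "b" for recs in comp.provenance.values() for rec in recs
        )

    def test_disjoint_edge_sets_concatenate(self):
        a = make_net(4, [(0, 1, 1.0)], name="a")
        b = make_net(4, [(2, 3, 1.0)], name="b")
        comp = combine([a, b], weight_equal([a, b]))
        assert comp.adjacency.nnz == a.adjacency.nnz + b.adjacency.nnz

    def test_dimension_mismatch_is_error(self):
        a = make_net(3, [(0, 1, 1.0)], name="a")
        b = make_net(4, [(0, 1, 1.0)], name="b")
        with pytest.raises(ValueError, match="dimension"):
            combine([a, b], NetworkWeights({"a": 1, "b": 1}, "equal"))

    def test_missing_weight_is_error(self):
        a = make_net(3, [(0, 1, 1.0)], name="a")
        with pytest.raises(ValueError, match="no weight"):
            combine([a], NetworkWeights({"other": 1.0}, "equal"))

    def test_combine_is_linear_in_weights(self, rng):
        from funcnet.network import random_network

        nets = [random_network(10, 0.3, rng) for _ in range(2)]
        nets[0].meta.name, nets[1].meta.name = "x", "y"
        wa = NetworkWeights({"x": 0.2, "y": 0.7}, "equal")
        wb = NetworkWeights({"x": 0.5, "y": 0.1}, "equal")
        wsum = NetworkWeights({"x": 0.7, "y": 0.8}, "equal")
        lhs = combine(nets, wsum).adjacency.toarray()
        rhs = combine(nets, wa).adjacency.toarray() + combine(nets, wb).adjacency.toarray()
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_composite_entry_matches_provenance_sum(self, rng):
        from funcnet.network import random_network

        nets = [random_network(12, 0.4, rng) for _ in range(3)]
        for k, net in enumerate(nets):
            net.meta.name = f"n{k}"
        comp = combine(nets, weight_equal(nets))
        for (i, j), recs in comp.provenance.items():
            assert comp.adjacency[i, j] == pytest.approx(
                sum(r.contribution for r in recs), abs=1e-9
            )


class TestCollapseForDisplay:
    def test_one_display_edge_per_group(self):
        # five co-expression + two physical-interaction networks sharing a pair
        nets = []
        for i in range(5):
            nets.append(make_net(4, [(0, 1, 0.5 + 0.1 * i)], name=f"coexp{i}", group="co-expression"))
        for i in range(2):
            nets.append(make_net(4, [(0, 1, 0.9)], name=f"ppi{i}", group="physical-interaction"))
        comp = combine(nets, weight_equal(nets))
        edges = [e for e in collapse_for_display(comp, [0, 1]) if (e.gene_i, e.gene_j) == (0, 1)]
        assert len(edges) == 2
        groups = {e.group for e in edges}
        assert groups == {"co-expression", "physical-interaction"}
        by_group = {e.group: e for e in edges}
        assert len(by_group["co-expression"].sources) == 5
        assert len(by_group["physical-interaction"].sources) == 2

    def test_single_source_weight_is_alpha_times_normalized(self):
        net = make_net(3, [(0, 1, 1.0), (1, 2, 1.0)], name="solo", group="coexp")
        comp = combine([net], NetworkWeights({"solo": 0.4}, "equal"))
        edges = collapse_for_display(comp, [0, 1, 2])
        norm = normalize_symmetric(net).adjacency
        for e in edges:
            assert e.weight == pytest.approx(0.4 * norm[e.gene_i, e.gene_j])

    def test_pairs_outside_subset_excluded(self):
        net = make_net(4, [(0, 1, 1.0), (2, 3, 1.0)], name="n", group="g")
        comp = combine([net], weight_equal([net]))
        edges = collapse_for_display(comp, [0, 1])
        assert [(e.gene_i, e.gene_j) for e in edges] == [(0, 1)]

    def test_conservation_display_sums_to_composite(self, rng):
        from funcnet.network import random_network

        nets = [random_network(15, 0.3, rng) for _ in range(4)]
        for k, net in enumerate(nets):
            net.meta.name = f"n{k}"
            net.meta.group = ["coexp", "ppi"][k % 2]
        comp = combine(nets, weight_by_group(nets))
        edges = collapse_for_display(comp, range(15))
        sums: dict[tuple[int, int], float] = {}
        for e in edges:
            sums[(e.gene_i, e.gene_j)] = sums.get((e.gene_i, e.gene_j), 0.0) + e.weight
        upper = sp.triu(comp.adjacency, 1).tocoo()
        assert len(sums) == upper.nnz
        for i, j, v in zip(upper.row, upper.col, upper.data):
            assert sums[(int(i), int(j))] == pytest.approx(v, abs=1e-9)

    def test_sources_carry_raw_weights_and_publication(self):
        net = make_net(3, [(0, 1, 2.5), (1, 2, 1.0)], name="n", group="g",
                       publication="Smith et al. 2010")
        comp = combine([net], weight_equal([net]))
        edge = [e for e in collapse_for_display(comp, [0, 1, 2])
                if (e.gene_i, e.gene_j) == (0, 1)][0]
        assert edge.sources == [("n", 2.5, "Smith et al. 2010")]
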