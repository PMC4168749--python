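"""Edge-list parsing, symmetric normalization, binary round trips."""

import numpy as np
import pytest
import scipy.sparse as sp

from funcnet import (
    NetworkMeta,
    normalize_symmetric,
    read_binary,
    read_edge_list,
    write_binary,
)
from funcnet.errors import BinaryFormatError, EdgeListError
from funcnet.network import random_network

from _helpers import make_net


def write(tmp_path, text, name="edges.tsv"):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestReadEdgeList:
    def test_single_edge_symmetric(self, tmp_path, universe, meta):
        net, report = read_edge_list(write(tmp_path, "G1\tG2\t0.5\n"), universe, meta)
        assert net.adjacency[0, 1] == net.adjacency[1, 0] == 0.5
        assert report.n_edges == 1

    def test_duplicate_pairs_summed_either_orientation(self, tmp_path, universe, meta):
        net, report = read_edge_list(
            write(tmp_path, "G1\tG2\t0.3\nG2\tG1\t0.5\n"), universe, meta
        )
        assert net.adjacency[0, 1] == pytest.approx(0.8)
        assert report.n_duplicate_pairs_merged == 1

    def test_missing_weight_defaults_to_one(self, tmp_path, universe, meta):
        net, _ = read_edge_list(write(tmp_path, "G1\tG2\n"), universe, meta)
        assert net.adjacency[0, 1] == 1.0

    def test_synonyms_resolve(self, tmp_path, universe, meta):
        net, _ = read_edge_list(write(tmp_path, "alpha\tBETA\t2\n"), universe, meta)
        assert net.adjacency[0, 1] == 2.0

    def test_self_edges_dropped_and_counted(self, tmp_path, universe, meta):
        net, report = read_edge_list(
            write(tmp_path, "G1\tG1\t1\nG1\tG2\t1\n"), universe, meta
        )
        assert report.n_self_edges_dropped == 1
        assert net.adjacency.diagonal().sum() == 0

    def test_only_self_edges_is_error(self, tmp_path, universe, meta):
        with pytest.raises(EdgeListError, match="no resolvable edges"):
            read_edge_list(write(tmp_path, "G1\tG1\t1.0\n"), universe, meta)

    def test_negative_weight_error_names_line(self, tmp_path, universe, meta):
        with pytest.raises(EdgeListError, match=":2:"):
            read_edge_list(write(tmp_path, "G1\tG2\t1\nG1\tG3\t-2\n"), universe, meta)

    def test_non_numeric_weight_error_names_line(self, tmp_path, universe, meta):
        with pytest.raises(EdgeListError, match=":1:"):
            read_edge_list(write(tmp_path, "G1\tG2\tmuch\n"), universe, meta)

    def test_unresolvable_genes_skipped_with_report(self, tmp_path, universe, meta):
        net, report = read_edge_list(
            write(tmp_path, "G1\tG2\t1\nG1\tUNKNOWN\t1\n"), universe, meta
        )
        assert report.n_unresolved_lines == 1
        assert report.unresolved_names == ["UNKNOWN"]
        assert net.nnz_pairs == 1

    def test_row_order_invariance(self, tmp_path, universe, meta):
        lines = ["G1\tG2\t0.3", "G2\tG3\t0.7", "G1\tG4\t0.1", "G2\tG1\t0.2"]
        a, _ = read_edge_list(write(tmp_path, "\n".join(lines) + "\n", "a.tsv"), universe, meta)
        b, _ = read_edge_list(
            write(tmp_path, "\n".join(reversed(lines)) + "\n", "b.tsv"), universe, meta
        )
        assert (a.adjacency != b.adjacency).nnz == 0


class TestNormalizeSymmetric:
    def test_single_edge_normalizes_to_one(self):
        for w in (0.1, 1.0, 7.3):
            net = make_net(2, [(0, 1, w)])
            norm = normalize_symmetric(net)
            assert norm.adjacency[0, 1] == pytest.approx(1.0)

    def test_path_graph_matches_dense_oracle(self):
        # A-B-C unit weights: degree of B is 2, so (A,B) -> 1/sqrt(2)
        net = make_net(3, [(0, 1, 1.0), (1, 2, 1.0)])
        norm = normalize_symmetric(net)
        assert norm.adjacency[0, 1] == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        w = net.adjacency.toarray()
        d = np.diag(1 / np.sqrt(w.sum(axis=1)))
        assert np.allclose(norm.adjacency.toarray(), d @ w @ d, atol=1e-12)

    def test_isolated_gene_row_stays_zero(self):
        net = make_net(3, [(0, 1, 1.0)])
        norm = normalize_symmetric(net)
        assert norm.adjacency[2].nnz == 0

    def test_spectral_radius_at_most_one(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 20))
            net = random_network(n, 0.4, rng)
            dense = normalize_symmetric(net).adjacency.toarray()
            eigs = np.linalg.eigvalsh(dense)
            assert np.abs(eigs).max() <= 1 + 1e-10
            assert np.abs(dense).max() <= 1 + 1e-12

    def test_output_symmetric(self, rng):
        net = random_network(15, 0.3, rng)
        norm = normalize_symmetric(net).adjacency
        assert (norm != norm.T).nnz == 0


class TestBinaryRoundTrip:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        net = random_network(
            23, 0.3, rng,
            NetworkMeta(name="rt", group="physical-interaction",
                        source_description="desc", publication="pub",
                        open_license=False, default_selected=False),
        )
        path = tmp_path / "net.gmnw"
        write_binary(net, path)
        again = read_binary(path)
        assert (again.adjacency != net.adjacency).nnz == 0
        assert np.array_equal(
            sp.triu(again.adjacency, 1).tocsr().data,
            sp.triu(net.adjacency, 1).tocsr().data,
        )
        assert again.meta == net.meta

    def test_empty_network_round_trip(self, tmp_path):
        net = make_net(7, [])
        path = tmp_path / "empty.gmnw"
        write_binary(net, path)
        again = read_binary(path)
        assert again.n == 7 and again.adjacency.nnz == 0

    def test_bad_magic_rejected(self, tmp_path):
        p = tmp_path / "bad.gmnw"
        p.write_bytes(b"NOPE" + bytes(60))
        with pytest.raises(BinaryFormatError, match="magic"):
            read_binary(p)

    def test_truncated_file_rejected(self, tmp_path, rng):
        net = random_network(10, 0.5, rng)
        p = tmp_path / "trunc.gmnw"
        write_binary(net, p)
        data = p.read_bytes()
        p.write_bytes(data[: len(data) // 2])
        with pytest.raises(BinaryFormatError, match="truncated"):
            read_binary(p)

    def test_universe_dimension_mismatch_rejected(self, tmp_path, universe, rng):
        net = random_network(9, 0.5, rng)  # universe has 5 genes
        p = tmp_path / "mismatch.gmnw"
        write_binary(net, p)
        with pytest.raises(BinaryFormatError, match="universe"):
            read_binary(p, universe)
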