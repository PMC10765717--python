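"""Correlation testing, network assembly rules, and export round trips."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import networkx as nx

from seedregnet import (
    ExpressionMatrix,
    build_network,
    export_network,
    family_summary,
    pearson_test,
    seed_design,
    subnetwork,
)
from seedregnet.errors import DegenerateInputError, ParameterError, ValidationError
from seedregnet.network import (
    REGIMES,
    RegulatoryEdge,
    RegulatoryNetwork,
    read_edge_tsv,
)


class TestPearson:
    def test_perfect_positive(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        r, p = pearson_test(x, x)
        assert (r, p) == (1.0, 0.0)

    def test_perfect_negative(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        r, _p = pearson_test(x, -x)
        assert r == -1.0

    def test_closed_form_two_df_case(self):
        # with n=4 the t CDF has the closed form P(T>t) = (1 - t/sqrt(2+t^2))/2
        r, p = pearson_test(np.array([1.0, 2, 3, 4]), np.array([1.0, 3, 2, 4]))
        assert r == pytest.approx(0.8, abs=1e-12)
        assert p == pytest.approx(0.2, abs=1e-12)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pearson_test(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            pearson_test(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_matches_permutation_null(self):
        """The t-based p-value tracks an exact permutation null at small n."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        y = 0.6 * x + rng.normal(size=10)
        r_obs, p_t = pearson_test(x, y)
        n_perm = 10_000
        count = 0
        for _ in range(n_perm):
            r_perm = np.corrcoef(x, rng.permutation(y))[0, 1]
            count += abs(r_perm) >= abs(r_obs)
        p_perm = count / n_perm
        assert p_t == pytest.approx(p_perm, abs=0.01)


def _expr(rows: dict[str, list[float]]) -> ExpressionMatrix:
    n = len(next(iter(rows.values())))
    design = (seed_design() + [])[:n]
    return ExpressionMatrix(
        pd.DataFrame(rows, index=[d.sample_id for d in design]).T,
        design, unit="TPM",
    )


class TestBuildNetwork:
    def _toy(self, rng):
        x = rng.normal(10.0, 1.0, size=8).tolist()
        rows = {
            "tf1": x,
            "tf2": rng.normal(10.0, 1.0, size=8).tolist(),
            "g1": (np.array(x) + rng.normal(0, 0.05, 8)).tolist(),  # tracks tf1
            "g2": rng.normal(10.0, 1.0, size=8).tolist(),
        }
        tf = _expr({k: rows[k] for k in ("tf1", "tf2")})
        sg = _expr({k: rows[k] for k in ("g1", "g2")})
        presence = pd.DataFrame(
            [[1, 1], [1, 1]], index=["tf1", "tf2"], columns=["g1", "g2"]
        )
        return tf, sg, presence

    def test_strong_correlation_with_tfbs_is_an_edge(self, rng):
        tf, sg, presence = self._toy(rng)
        net = build_network(tf, sg, presence, r_min=0.95, p_max=0.05)
        assert ("tf1", "g1") in net.edge_pairs()

    def test_no_tfbs_blocks_even_perfect_correlation(self, rng):
        tf, sg, presence = self._toy(rng)
        presence.loc["tf1", "g1"] = 0
        net = build_network(tf, sg, presence, r_min=0.8, p_max=0.05)
        assert ("tf1", "g1") not in net.edge_pairs()

    def test_edges_anti_monotone_in_r_min(self, rng):
        tf, sg, presence = self._toy(rng)
        loose = build_network(tf, sg, presence, r_min=0.5).edge_pairs()
        tight = build_network(tf, sg, presence, r_min=0.9).edge_pairs()
        assert tight <= loose

    def test_edges_monotone_in_p_max(self, rng):
        tf, sg, presence = self._toy(rng)
        small = build_network(tf, sg, presence, r_min=0.5, p_max=0.001).edge_pairs()
        large = build_network(tf, sg, presence, r_min=0.5, p_max=0.2).edge_pairs()
        assert small <= large

    def test_negative_correlation_excluded_by_signed_threshold(self):
        x = [1.0, 2, 3, 4, 5, 6, 7, 8]
        tf = _expr({"tf1": x})
        sg = _expr({"g1": [9.0 - v for v in x]})
        presence = pd.DataFrame([[1]], index=["tf1"], columns=["g1"])
        net = build_network(tf, sg, presence, r_min=0.8)
        assert net.n_edges == 0

    def test_order_independence(self, rng):
        tf, sg, presence = self._toy(rng)
        net1 = build_network(tf, sg, presence, r_min=0.5)
        sg_rev = _expr(
            {k: sg.values.loc[k].tolist() for k in reversed(sg.feature_ids)}
        )
        net2 = build_network(tf, sg_rev, presence, r_min=0.5)
        assert net1.edge_pairs() == net2.edge_pairs()

    def test_same_cluster_constraint_excludes_cross_cluster_pairs(self, rng):
        from seedregnet.cluster import ClusterAssignment

        tf, sg, presence = self._toy(rng)
        labels = pd.Series({"tf1": 1, "tf2": 1, "g1": 2, "g2": 1})
        ca = ClusterAssignment(
            list(labels.index), labels,
            pd.DataFrame(np.zeros((2, 4)), index=[1, 2]), 2, 0.0, 0,
        )
        net = build_network(tf, sg, presence, r_min=0.5, same_cluster=ca)
        assert all(labels[e.tf_id] == labels[e.gene_id] for e in net.edges)
        assert ("tf1", "g1") not in net.edge_pairs()

    def test_aggregate_groups_uses_group_means(self, small_tpm, small_bundle):
        truth = small_bundle["truth"]
        presence = pd.DataFrame(
            1, index=truth.tf_ids, columns=truth.structural_gene_ids
        )
        net = build_network(
            small_tpm.subset(truth.tf_ids),
            small_tpm.subset(truth.structural_gene_ids),
            presence, r_min=0.8, aggregate_groups=True,
        )
        assert all(e.n_obs == 8 for e in net.edges)
        assert net.n_edges > 0

    def test_empty_candidate_set_is_empty_network(self):
        tf = _expr({"tf1": [1.0, 2, 3, 7]})
        sg = _expr({"g1": [1.0, 2, 3, 7.5]})
        presence = pd.DataFrame([[0]], index=["tf1"], columns=["g1"])
        net = build_network(tf, sg, presence, r_min=0.8)
        assert net.n_edges == 0 and "g1" in net.gene_nodes

    def test_regime_presets_match_study_thresholds(self):
        assert REGIMES["cluster_seed"]["r_min"] == 0.95
        assert REGIMES["multi_tissue"]["r_min"] == 0.8
        assert all(v["p_max"] == 0.05 for v in REGIMES.values())


def _toy_net() -> RegulatoryNetwork:
    edges = [
        RegulatoryEdge("tf1", "g1", 0.97, 0.001, 16, True, "MYB"),
        RegulatoryEdge("tf1", "g2", 0.91, 0.004, 16, True, "MYB"),
        RegulatoryEdge("tf2", "g1", 0.88, 0.01, 16, True, "bHLH"),
        RegulatoryEdge("tf3", "g1", 0.85, 0.02, 16, True, "MYB"),
    ]
    fams = {"tf1": "MYB", "tf2": "bHLH", "tf3": "MYB"}
    return RegulatoryNetwork(
        edges, {"tf1", "tf2", "tf3"}, {"g1", "g2", "g3"}, "custom", (0.8, 0.05), fams
    )


class TestSubnetworkAndSummary:
    def test_focal_all_genes_is_identity(self):
        net = _toy_net()
        sub = subnetwork(net, net.gene_nodes)
        assert sub.edge_pairs() == net.edge_pairs()

    def test_single_gene_star(self):
        sub = subnetwork(_toy_net(), {"g1"})
        assert sub.edge_pairs() == {("tf1", "g1"), ("tf2", "g1"), ("tf3", "g1")}

    def test_isolated_focal_gene_kept_as_node(self):
        sub = subnetwork(_toy_net(), {"g3"})
        assert sub.n_edges == 0 and "g3" in sub.gene_nodes

    def test_unknown_focal_id_named_in_error(self):
        with pytest.raises(ValidationError, match="gX"):
            subnetwork(_toy_net(), {"gX"})

    def test_family_summary_counts_and_ordering(self):
        df = family_summary(_toy_net())
        assert df["family"].tolist() == ["MYB", "bHLH"]
        assert df["n_tfs"].tolist() == [2, 1]
        assert df["n_edges"].tolist() == [3, 1]
        # partition: family TF counts sum to distinct TF nodes
        assert df["n_tfs"].sum() == len({e.tf_id for e in _toy_net().edges})

    def test_empty_network_gives_empty_table(self):
        net = RegulatoryNetwork([], set(), set(), "custom", (0.8, 0.05))
        assert family_summary(net).empty


class TestExport:
    def test_sif_lines(self, tmp_path):
        net = _toy_net()
        path = tmp_path / "net.sif"
        export_network(net, path, "SIF")
        lines = path.read_text().strip().split("\n")
        assert len(lines) == net.n_edges
        assert lines[0].split() == ["tf1", "regulates", "g1"]

    def test_graphml_round_trips_attributes(self, tmp_path):
        path = tmp_path / "net.graphml"
        export_network(_toy_net(), path, "GraphML")
        g = nx.read_graphml(path)
        assert g.edges[("tf1", "g1")]["pcc"] == pytest.approx(0.97)
        assert g.nodes["tf1"]["family"] == "MYB"

    def test_edge_tsv_round_trip_preserves_pcc(self, tmp_path):
        net = _toy_net()
        path = tmp_path / "net.tsv"
        export_network(net, path, "edge-TSV")
        back = read_edge_tsv(path)
        assert back.edge_pairs() == net.edge_pairs()
        pcc_in = {(e.tf_id, e.gene_id): e.pcc for e in net.edges}
        for e in back.edges:
            assert e.pcc == pytest.approx(pcc_in[(e.tf_id, e.gene_id)], rel=1e-11)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ParameterError):
            export_network(_toy_net(), tmp_path / "x", "dot")
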