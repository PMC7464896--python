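import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circsponge import diffexpr as de
from circsponge import network as net
from circsponge.annotate import classify_all, log2_cpm
from circsponge.model import PipelineError
from conftest import make_matrix
from oracles import pearson_oracle, triplet_count_oracle


class TestPearsonWithP:
    def test_perfect_positive(self):
        r, p = net.pearson_with_p([1, 2, 3, 4], [1, 2, 3, 4])
        assert (r, p) == (1.0, 0.0)

    def test_perfect_negative(self):
        r, p = net.pearson_with_p([1, 2, 3, 4], [-1, -2, -3, -4])
        assert (r, p) == (-1.0, 0.0)

    def test_matches_direct_formula_and_scipy(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 5.0]
        r, p = net.pearson_with_p(x, y)
        assert r == pytest.approx(pearson_oracle(x, y), abs=1e-12)
        sp = stats.pearsonr(x, y)
        assert r == pytest.approx(sp.statistic, abs=1e-12)
        assert p == pytest.approx(sp.pvalue, rel=1e-9)

    def test_zero_variance_is_error(self):
        with pytest.raises(PipelineError, match="variance"):
            net.pearson_with_p([1, 1, 1], [1, 2, 3])

    def test_short_input_is_error(self):
        with pytest.raises(PipelineError):
            net.pearson_with_p([1, 2], [3, 4])


class TestCoexpressionMap:
    def test_all_pairs_tested(self):
        rng = np.random.default_rng(0)
        circ = make_matrix(rng.poisson(100, size=(2, 6)))
        mrna = make_matrix(rng.poisson(100, size=(3, 6)))
        edges = net.coexpression_map(circ, mrna)
        assert len(edges) == 6

    def test_sample_mismatch_is_error(self):
        circ = make_matrix([[1, 2]], samples=["a", "b"])
        mrna = make_matrix([[1, 2]], samples=["a", "c"])
        with pytest.raises(PipelineError):
            net.coexpression_map(circ, mrna)

    def test_vectorized_map_agrees_with_scalar_op(self):
        rng = np.random.default_rng(3)
        circ = make_matrix(rng.poisson(200, size=(4, 20)))
        mrna = make_matrix(rng.poisson(200, size=(5, 20)))
        edges = net.coexpression_map(circ, mrna)
        lc, lm = log2_cpm(circ), log2_cpm(mrna)
        for e in edges.itertuples(index=False):
            r, p = net.pearson_with_p(lc.loc[e.circ_id], lm.loc[e.mrna_id])
            assert e.r == pytest.approx(r, abs=1e-10)
            assert e.p == pytest.approx(p, abs=1e-10)

    def test_planted_pair_retained_under_both_modes(self, default_cohort):
        c = default_cohort
        trip_circ, _, trip_gene = c.truth.planted_triplets[1]
        for mode in ("p", "padj"):
            edges = net.coexpression_map(
                c.circ_matrix, c.mrna_matrix, net.CoexprConfig(mode=mode),
                circ_features=[trip_circ])
            row = edges[(edges["circ_id"] == trip_circ) & (edges["mrna_id"] == trip_gene)]
            assert bool(row["retained"].iloc[0])

    def test_padj_mode_requires_positive_r(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        stab_c = rng.poisson(5000, size=30)  # keeps CPM totals informative
        stab_m = rng.poisson(5000, size=30)
        circ = make_matrix(np.vstack([np.round(500 * np.exp(x)),
                                      np.round(500 * np.exp(-x)),
                                      stab_c]).astype(int))
        mrna = make_matrix(np.vstack([np.round(500 * np.exp(x)),
                                      stab_m]).astype(int))
        edges = net.coexpression_map(circ, mrna, net.CoexprConfig(mode="padj"))
        keyed = edges.set_index(["circ_id", "mrna_id"])
        assert keyed.loc[("f0", "f0"), "padj"] < 0.05
        assert bool(keyed.loc[("f0", "f0"), "retained"])      # r > 0
        assert keyed.loc[("f1", "f0"), "r"] < 0
        assert not bool(keyed.loc[("f1", "f0"), "retained"])  # r < 0 despite tiny padj


class TestHostCorrelation:
    def test_host_positively_correlated_and_intergenic_skipped(self, default_cohort):
        c = default_cohort
        junctions = classify_all(c.junctions, c.annotation)
        table = net.host_correlation_map(c.circ_matrix, c.mrna_matrix, junctions)
        intergenic = {j.circ_id for j in junctions if j.structural_class == "intergenic"}
        assert intergenic.isdisjoint(set(table["circ_id"]))
        assert len(table) == len(junctions) - len(intergenic)
        # hosts share their circRNA's latent factor: positive r on average
        assert table["r"].median() > 0.2
        assert (table["r"] > 0).mean() > 0.9


def _edges(rows):
    return pd.DataFrame(rows, columns=["circ_id", "mrna_id", "r", "p", "padj", "n", "retained"])


def _sites(rows):
    return pd.DataFrame(rows, columns=["target_id", "target_kind", "mirna_id", "n_sites"])


class TestBuildTriplets:
    def test_requires_two_circ_sites_one_utr_site_and_positive_r(self):
        edges = _edges([("c1", "g1", 0.6, 1e-4, 1e-3, 39, True),
                        ("c2", "g1", -0.6, 1e-4, 1e-3, 39, True)])
        site_table = _sites([("c1", "circ", "m1", 2),
                             ("c1", "circ", "m2", 1),       # one circ hit only
                             ("c2", "circ", "m1", 2),
                             ("g1", "utr3", "m1", 1),
                             ("g1", "utr3", "m2", 1)])
        triplets = net.build_triplets(edges, site_table)
        assert len(triplets) == 1
        row = triplets.iloc[0]
        assert (row["circ_id"], row["mirna_id"], row["mrna_id"]) == ("c1", "m1", "g1")
        assert row["n_sites_circ"] == 2 and row["n_sites_utr"] == 1

    def test_unretained_edge_yields_nothing(self):
        edges = _edges([("c1", "g1", 0.6, 0.2, 0.4, 39, False)])
        site_table = _sites([("c1", "circ", "m1", 2), ("g1", "utr3", "m1", 1)])
        assert len(net.build_triplets(edges, site_table)) == 0

    def test_count_matches_brute_force_triple_loop(self):
        rng = np.random.default_rng(11)
        circ_ids = [f"c{i}" for i in range(10)]
        mirna_ids = [f"m{i}" for i in range(10)]
        mrna_ids = [f"g{i}" for i in range(20)]
        edge_rows, site_rows = [], []
        for c in circ_ids:
            for g in mrna_ids:
                edge_rows.append((c, g, float(rng.uniform(-1, 1)), 0.01, 0.02, 39,
                                  bool(rng.random() < 0.5)))
        for c in circ_ids:
            for m in mirna_ids:
                if rng.random() < 0.4:
                    site_rows.append((c, "circ", m, int(rng.integers(1, 4))))
        for g in mrna_ids:
            for m in mirna_ids:
                if rng.random() < 0.4:
                    site_rows.append((g, "utr3", m, int(rng.integers(1, 3))))
        edges, site_table = _edges(edge_rows), _sites(site_rows)
        expect = triplet_count_oracle(edges.to_dict("records"), site_table.to_dict("records"))
        assert len(net.build_triplets(edges, site_table)) == expect


class TestNetworkSummary:
    def test_shared_nodes(self):
        triplets = pd.DataFrame(
            [("c1", "m1", f"g{i}", 2, 1, 0.5, 0.01, 0.02) for i in range(3)],
            columns=net.TRIPLET_COLUMNS)
        assert net.network_summary(triplets) == {
            "n_triplets": 3, "n_unique_circ": 1, "n_unique_mirna": 1, "n_unique_mrna": 3}

    def test_empty(self):
        empty = pd.DataFrame(columns=net.TRIPLET_COLUMNS)
        assert net.network_summary(empty) == {
            "n_triplets": 0, "n_unique_circ": 0, "n_unique_mirna": 0, "n_unique_mrna": 0}


class TestCallTargets:
    def _kd(self, rows):
        df = pd.DataFrame(rows, columns=["feature_id", "log2fc", "p", "padj"])
        df["direction"] = np.where(df["log2fc"] > 0, "up", "down")
        return df.set_index("feature_id")

    def test_sign_and_direction_rules(self):
        edges = _edges([("c1", "gPos", 0.5, 0.01, 0.02, 39, True),
                        ("c1", "gNeg", -0.5, 0.01, 0.02, 39, True),
                        ("c1", "gWrong", 0.5, 0.01, 0.02, 39, True)])
        kd = self._kd([("gPos", -1.2, 0.01, 0.02),
                       ("gNeg", 0.9, 0.01, 0.02),
                       ("gWrong", 0.8, 0.01, 0.02)])   # positive r but UP on KD
        calls = net.call_targets("c1", edges, kd)
        got = dict(zip(calls["gene_id"], calls["call_class"]))
        assert got == {"gPos": "positively_regulated", "gNeg": "negatively_regulated"}

    def test_classes_are_disjoint_and_consistent(self):
        edges = _edges([("c1", "g1", 0.5, 0.01, 0.02, 39, True)])
        kd = self._kd([("g1", -2.0, 0.001, 0.01)])
        calls = net.call_targets("c1", edges, kd)
        for row in calls.itertuples(index=False):
            if row.call_class == "positively_regulated":
                assert row.r > 0 and row.kd_log2fc < 0
            else:
                assert row.r < 0 and row.kd_log2fc > 0

    def test_empty_intersection(self):
        edges = _edges([("c1", "g1", 0.5, 0.01, 0.02, 39, True)])
        assert len(net.call_targets("c1", edges, self._kd([]))) == 0

    def test_unknown_circ_is_error(self):
        edges = _edges([("c1", "g1", 0.5, 0.01, 0.02, 39, True)])
        with pytest.raises(PipelineError):
            net.call_targets("cX", edges, self._kd([]))


class TestExportNetwork:
    TRIPLET = pd.DataFrame([("c1", "m1", "g1", 2, 1, 0.5, 0.01, 0.02)],
                           columns=net.TRIPLET_COLUMNS)

    def test_graphml_two_edges_three_nodes(self, tmp_path):
        import networkx as nx
        path = tmp_path / "n.graphml"
        net.export_network(self.TRIPLET, path, "graphml")
        g = nx.read_graphml(path)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
        kinds = {d["kind"] for _, d in g.nodes(data=True)}
        assert kinds == {"circRNA", "miRNA", "mRNA"}

    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "t.tsv"
        net.export_network(self.TRIPLET, path, "tsv")
        back = net.read_network_tsv(path)
        pd.testing.assert_frame_equal(back, self.TRIPLET)

    def test_unknown_format_is_error(self, tmp_path):
        with pytest.raises(PipelineError):
            net.export_network(self.TRIPLET, tmp_path / "x", "xlsx")
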