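"""Signed Pearson relevance network: correlation, thresholded edges, hub
ranking, neighborhoods and module correlation."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coexpair import (
    ExpressionMatrix,
    GeneSetCollection,
    build_network,
    correlation_matrix,
    generate_cohort,
    hub_neighborhood,
    module_correlation,
    select_hubs,
)
from coexpair.network import CoexpressionNetwork, CorrelationMatrix, HubReport
from coexpair.simulate import SimulationConfig
from tests.conftest import paired_cohort


def _de_frame(genes, direction="up", log2_fc=2.0):
    return pd.DataFrame(
        {
            "fold_change": [2.0 ** log2_fc] * len(genes),
            "log2_fc": [log2_fc] * len(genes),
            "direction": [direction] * len(genes),
        },
        index=list(genes),
    )


class TestCorrelationMatrix:
    def test_duplicated_gene_correlates_perfectly_with_twin(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 100, size=12)
        values = pd.DataFrame([x, x, rng.uniform(1, 100, size=12)],
                              index=["g", "twin", "other"],
                              columns=[f"s{i}" for i in range(12)])
        cm = correlation_matrix(ExpressionMatrix(values))
        assert cm.values.loc["g", "twin"] == pytest.approx(1.0, abs=1e-12)

    def test_monotone_decreasing_affine_transform_gives_minus_one(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(1, 50, size=10)
        log2p1 = np.log2(x + 1)
        flipped = 2.0 ** (-2.0 * log2p1 + 20.0) - 1.0  # negative affine on log scale
        values = pd.DataFrame([x, flipped], index=["g", "anti"],
                              columns=[f"s{i}" for i in range(10)])
        cm = correlation_matrix(ExpressionMatrix(values))
        assert cm.values.loc["g", "anti"] == pytest.approx(-1.0, abs=1e-10)

    def test_matches_two_pass_covariance_oracle(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(rng.uniform(0, 100, size=(50, 20)),
                              index=[f"g{i}" for i in range(50)],
                              columns=[f"s{i}" for i in range(20)])
        cm = correlation_matrix(ExpressionMatrix(values))
        X = np.log2(values.to_numpy() + 1)
        n = X.shape[1]
        mean = X.mean(axis=1)
        for i in range(0, 50, 7):
            for j in range(0, 50, 11):
                cov = ((X[i] - mean[i]) * (X[j] - mean[j])).sum() / n
                sd_i = np.sqrt(((X[i] - mean[i]) ** 2).sum() / n)
                sd_j = np.sqrt(((X[j] - mean[j]) ** 2).sum() / n)
                assert cm.values.iloc[i, j] == pytest.approx(cov / (sd_i * sd_j),
                                                             abs=1e-12)

    def test_constant_genes_dropped_with_warning(self, caplog):
        values = pd.DataFrame([[3.0] * 5, [1, 2, 3, 4, 5], [5, 4, 3, 2, 1]],
                              index=["flat", "a", "b"],
                              columns=[f"s{i}" for i in range(5)])
        with caplog.at_level("WARNING"):
            cm = correlation_matrix(ExpressionMatrix(values))
        assert "flat" not in cm.gene_ids
        assert any("flat" in r.message for r in caplog.records)

    def test_fewer_than_three_samples_rejected(self):
        values = pd.DataFrame([[1, 2], [3, 4]], index=["a", "b"],
                              columns=["s1", "s2"])
        with pytest.raises(ValueError, match="3 samples"):
            correlation_matrix(ExpressionMatrix(values))

    def test_tumors_only_mode_uses_tumor_samples(self, small_paired_cohort):
        matrix, metadata = small_paired_cohort
        cm = correlation_matrix(matrix, samples="tumors", metadata=metadata)
        assert cm.n_samples == 12
        assert cm.sample_set == "tumors"


class TestBuildNetwork:
    def _cm(self, C, genes):
        return CorrelationMatrix(pd.DataFrame(C, index=genes, columns=genes),
                                 "all", 20)

    def test_cc_exactly_at_threshold_is_not_an_edge(self):
        C = np.array([[1.0, 0.8], [0.8, 1.0]])
        net = build_network(self._cm(C, ["a", "b"]), _de_frame(["a", "b"]), 0.8)
        assert net.n_edges == 0
        assert net.n_nodes == 0  # isolated genes are excluded

    def test_strong_negative_pair_gets_neg_edge(self):
        C = np.array([[1.0, -0.95], [-0.95, 1.0]])
        net = build_network(self._cm(C, ["a", "b"]), _de_frame(["a", "b"]), 0.8)
        assert net.n_edges == 1
        assert net.graph.edges[("a", "b")]["sign"] == "neg"

    def test_equals_brute_force_double_loop(self):
        matrix, metadata = paired_cohort(n_genes=100, n_pairs=12, seed=9)
        cm = correlation_matrix(matrix)
        de = _de_frame(cm.gene_ids)
        net = build_network(cm, de, threshold=0.3)
        expected = set()
        genes = cm.gene_ids
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if abs(cm.values.iloc[i, j]) > 0.3:
                    expected.add(frozenset((genes[i], genes[j])))
        got = {frozenset(e) for e in net.graph.edges}
        assert got == expected

    def test_threshold_domain_checked(self):
        C = np.eye(2)
        with pytest.raises(ValueError):
            build_network(self._cm(C, ["a", "b"]), _de_frame(["a", "b"]), 1.0)

    def test_degree_sum_is_twice_edge_count_and_no_isolated_nodes(self):
        matrix, metadata = paired_cohort(n_genes=80, n_pairs=10, seed=4)
        cm = correlation_matrix(matrix)
        net = build_network(cm, _de_frame(cm.gene_ids), threshold=0.4)
        degrees = dict(net.graph.degree)
        assert sum(degrees.values()) == 2 * net.n_edges
        assert all(d > 0 for d in degrees.values())

    def test_edge_count_monotone_in_threshold(self):
        matrix, metadata = paired_cohort(n_genes=60, n_pairs=10, seed=5)
        cm = correlation_matrix(matrix)
        de = _de_frame(cm.gene_ids)
        counts = [build_network(cm, de, threshold=t).n_edges
                  for t in (0.0, 0.2, 0.4, 0.6, 0.8, 0.95)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_sample_reordering_leaves_network_unchanged(self, small_paired_cohort):
        matrix, metadata = small_paired_cohort
        rng = np.random.default_rng(6)
        shuffled = list(matrix.sample_ids)
        rng.shuffle(shuffled)
        cm1 = correlation_matrix(matrix)
        cm2 = correlation_matrix(matrix.subset_samples(shuffled))
        de = _de_frame(cm1.gene_ids)
        e1 = build_network(cm1, de, 0.4).edges_table()
        e2 = build_network(cm2, de, 0.4).edges_table()
        pd.testing.assert_frame_equal(e1, e2, atol=1e-12)

    def test_negative_slope_flips_incident_signs_only(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=12)
        values = pd.DataFrame(
            [base * 1.0 + 5, base * 2.0 + 9, base * 0.5 + 3],
            index=["a", "b", "c"], columns=[f"s{i}" for i in range(12)])
        values += 20  # keep positive
        cm = correlation_matrix(ExpressionMatrix(values), log_transform=False)
        net = build_network(cm, _de_frame(["a", "b", "c"]), 0.8)
        flipped = values.copy()
        flipped.loc["c"] = -flipped.loc["c"] + 100.0
        cm_f = correlation_matrix(ExpressionMatrix(flipped), log_transform=False)
        net_f = build_network(cm_f, _de_frame(["a", "b", "c"]), 0.8)
        assert {frozenset(e) for e in net.graph.edges} == \
               {frozenset(e) for e in net_f.graph.edges}
        for u, v, d in net.graph.edges(data=True):
            sign_f = net_f.graph.edges[(u, v)]["sign"]
            if "c" in (u, v):
                assert sign_f != d["sign"]
            else:
                assert sign_f == d["sign"]


class TestHubs:
    def _network_with_degrees(self, spec):
        """Graph in which gene i gets exactly spec[i] neighbors (star spokes)."""
        g = nx.Graph()
        for gene, (degree, log2_fc, direction) in spec.items():
            g.add_node(gene, direction=direction, log2_fc=log2_fc,
                       fold_change=2.0 ** log2_fc)
            for k in range(degree):
                spoke = f"{gene}_n{k}"
                g.add_node(spoke, direction="up", log2_fc=1.5, fold_change=2.8)
                g.add_edge(gene, spoke, cc=0.9, sign="pos")
        return CoexpressionNetwork(graph=g, threshold=0.8)

    def test_ranking_follows_degree(self):
        spec = {g: (d, 2.0, "up") for g, d in
                [("A", 176), ("B", 150), ("C", 145), ("D", 109), ("E", 106),
                 ("F", 90)]}
        net = self._network_with_degrees(spec)
        report = select_hubs(net, k_per_direction=5)
        assert list(report.up["gene"])[:5] == ["A", "B", "C", "D", "E"]
        assert list(report.up["degree"]) == [176, 150, 145, 109, 106]

    def test_degree_tie_broken_by_fold_magnitude_then_name(self):
        spec = {"big": (10, -3.0, "up"), "small": (10, 1.0, "up"),
                "zz": (10, 1.0, "up")}
        net = self._network_with_degrees(spec)
        report = select_hubs(net, k_per_direction=3)
        assert list(report.up["gene"])[:3] == ["big", "small", "zz"]

    def test_empty_network_returns_empty_report_with_warning(self, caplog):
        net = CoexpressionNetwork(graph=nx.Graph(), threshold=0.8)
        with caplog.at_level("WARNING"):
            report = select_hubs(net)
        assert report.up.empty and report.down.empty

    def test_star_neighborhood_is_whole_star(self):
        net = self._network_with_degrees({"HUB": (6, 3.0, "up")})
        report = HubReport(
            up=pd.DataFrame({"gene": ["HUB"], "degree": [6], "log2_fc": [3.0],
                             "fold_change": [8.0]}),
            down=pd.DataFrame(columns=["gene", "degree", "log2_fc", "fold_change"]),
            k_per_direction=1,
        )
        sub = hub_neighborhood(net, report)
        assert sub.n_nodes == 7
        assert sub.n_edges == 6

    def test_isolated_hub_is_singleton_in_subnetwork(self):
        g = nx.Graph()
        g.add_node("LONER", direction="up", log2_fc=2.0, fold_change=4.0)
        net = CoexpressionNetwork(graph=g, threshold=0.8)
        report = HubReport(
            up=pd.DataFrame({"gene": ["LONER"], "degree": [0], "log2_fc": [2.0],
                             "fold_change": [4.0]}),
            down=pd.DataFrame(columns=["gene", "degree", "log2_fc", "fold_change"]),
            k_per_direction=1,
        )
        sub = hub_neighborhood(net, report)
        assert sub.n_nodes == 1 and sub.n_edges == 0


class TestModuleCorrelation:
    def test_module_against_itself_is_positive(self, small_paired_cohort):
        matrix, _ = small_paired_cohort
        modules = GeneSetCollection({"m": matrix.gene_ids[:5]})
        summary = module_correlation(matrix, modules)
        row = summary.iloc[0]
        assert row["eigengene_cc"] == 1.0
        assert row["classification"] == "positive"

    def test_small_module_rejected_by_name(self, small_paired_cohort):
        matrix, _ = small_paired_cohort
        modules = GeneSetCollection({"tiny": matrix.gene_ids[:2]})
        with pytest.raises(ValueError, match="tiny"):
            module_correlation(matrix, modules)

    def test_overlapping_modules_rejected(self, small_paired_cohort):
        matrix, _ = small_paired_cohort
        modules = GeneSetCollection({"a": matrix.gene_ids[:4],
                                     "b": matrix.gene_ids[2:8]})
        with pytest.raises(ValueError, match="overlap"):
            module_correlation(matrix, modules)

    def test_independent_modules_classified_none(self):
        hits = 0
        for seed in range(1, 21):
            cfg = SimulationConfig(n_genes=500, n_pairs=79, frac_de=0.0,
                                   hub_spec=(), n_modules=2, module_sizes=(30, 30),
                                   inter_module_corr=np.eye(2), seed=seed)
            matrix, _, truth = generate_cohort(cfg)
            summary = module_correlation(matrix, truth.modules())
            row = summary[summary.module_a != summary.module_b].iloc[0]
            hits += row["classification"] == "none"
        assert hits >= 19


class TestPlantedHubRecovery:
    def test_hub_neighborhoods_capture_planted_partners(self):
        """Planted hubs keep >= 80% of their partners as direct neighbors."""
        from coexpair import call_degs, de_table, filter_by_abundance

        for seed in range(1, 11):
            cfg = SimulationConfig(n_genes=2000, n_pairs=79, frac_de=0.35,
                                   fold_change_range=(2.0, 8.0),
                                   n_modules=0, module_sizes=(), seed=seed)
            matrix, metadata, truth = generate_cohort(cfg)
            abundant = filter_by_abundance(matrix)
            de = de_table(abundant, metadata)
            up, down = call_degs(de)
            degs = [g for g in de.index if g in up or g in down]
            cm = correlation_matrix(abundant, genes=degs, metadata=metadata)
            net = build_network(cm, de)
            for hub in truth.hub_genes:
                assert hub["gene"] in net.graph
                neighbors = set(net.graph.neighbors(hub["gene"]))
                frac = len(neighbors & set(hub["partners"])) / hub["n_partners"]
                assert frac >= 0.8
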