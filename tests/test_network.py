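"""Tests for dominance filtering, correlation edges with BH, modules,
module summaries and per-sample subnetworks."""

import itertools
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from strawcue.community import AsvTable, relative_abundance
from strawcue.errors import ConstantTaxonWarning, StrawCueWarning
from strawcue.network import (
    build_network,
    combine_domain_tables,
    correlation_edges,
    detect_modules,
    filter_dominant,
    module_sample_abundance,
    module_stats,
    sample_subnetwork,
)
from tests.conftest import brute_force_bh


def _brute_force_dominant(table, abund_threshold=0.001, prevalence_fraction=0.5):
    """Literal re-evaluation of both dominance criteria, ASV by ASV."""
    props = table.counts.div(table.counts.sum(axis=1), axis=0)
    keep = []
    for asv in table.counts.columns:
        mean_abund = props[asv].mean()
        prevalence = (table.counts[asv] > 0).sum() / table.n_samples
        if mean_abund > abund_threshold and prevalence > prevalence_fraction:
            keep.append(asv)
    return keep


class TestFilterDominant:
    def test_rare_asv_removed(self, toy_table):
        # asv_rare: ~0.3% of samples' reads but present in 2/6 samples only
        kept = filter_dominant(toy_table).counts.columns
        assert "asv_rare" not in kept

    def test_exactly_half_prevalence_removed(self, toy_table):
        # asv_halfprev is abundant but present in exactly 3 of 6 samples:
        # the rule is strictly "above half"
        kept = filter_dominant(toy_table).counts.columns
        assert "asv_halfprev" not in kept
        assert "asv_abundant" in kept

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n_s, n_a = int(rng.integers(4, 10)), int(rng.integers(3, 20))
            counts = pd.DataFrame(
                rng.integers(0, 40, size=(n_s, n_a))
                * rng.binomial(1, 0.7, size=(n_s, n_a)),
                index=[f"s{i}" for i in range(n_s)],
                columns=[f"a{j}" for j in range(n_a)],
            )
            counts.iloc[:, 0] += 1  # avoid zero-total samples
            tax = pd.DataFrame(
                {"phylum": ["P"] * n_a}, index=pd.Index(counts.columns, name="asv_id")
            )
            table = AsvTable(counts, tax, "bacterial")
            thr = float(rng.uniform(0.0, 0.1))
            prev = float(rng.uniform(0.2, 0.9))
            got = list(filter_dominant(table, thr, prev).counts.columns)
            assert got == _brute_force_dominant(table, thr, prev)

    def test_empty_table_passthrough(self, toy_table):
        empty = toy_table.subset_asvs([])
        assert filter_dominant(empty).n_asvs == 0

    def test_invalid_threshold_rejected(self, toy_table):
        with pytest.raises(ValueError):
            filter_dominant(toy_table, abund_threshold=1.5)


class TestCorrelationEdges:
    def test_perfect_rank_correlation_retained(self):
        x = np.arange(10, dtype=float)
        props = pd.DataFrame({"a": x, "b": x**2, "c": np.random.default_rng(0).normal(size=10)})
        edges = correlation_edges(props)
        ab = edges[(edges["i"] == "a") & (edges["j"] == "b")].iloc[0]
        assert ab["r"] == pytest.approx(1.0)
        assert ab["retained"]

    def test_bh_hand_example(self):
        raw = np.array([0.001, 0.008, 0.039, 0.041])
        adj = multipletests(raw, method="fdr_bh")[1]
        assert adj == pytest.approx([0.004, 0.016, 0.041, 0.041], abs=1e-12)
        assert brute_force_bh(raw) == pytest.approx(adj, abs=1e-12)

    def test_r_at_threshold_not_retained(self):
        # boundary: the rule is strictly |r| > 0.6
        x = np.arange(8, dtype=float)
        props = pd.DataFrame({"a": x, "b": x})
        edges = correlation_edges(props, r_threshold=1.0)
        assert not edges["retained"].any()

    def test_constant_column_excluded_with_warning(self):
        rng = np.random.default_rng(1)
        props = pd.DataFrame(
            {"a": rng.normal(size=8), "b": rng.normal(size=8), "flat": np.ones(8)}
        )
        with pytest.warns(ConstantTaxonWarning):
            edges = correlation_edges(props)
        assert "flat" not in set(edges["i"]) | set(edges["j"])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            correlation_edges(pd.DataFrame(np.ones((3, 4))))

    def test_bh_monotonicity_properties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            raw = rng.uniform(size=int(rng.integers(2, 60)))
            adj = multipletests(raw, method="fdr_bh")[1]
            assert (adj >= raw - 1e-15).all()
            assert (adj <= 1.0).all()
            order = np.argsort(raw)
            assert (np.diff(adj[order]) >= -1e-15).all()

    def test_joint_criteria_necessary(self):
        """Dropping either filter can only enlarge the edge set."""
        rng = np.random.default_rng(5)
        props = pd.DataFrame(rng.normal(size=(12, 10)))
        strict = correlation_edges(props, r_threshold=0.6, p_threshold=0.01)
        no_r = correlation_edges(props, r_threshold=0.0, p_threshold=0.01)
        no_p = correlation_edges(props, r_threshold=0.6, p_threshold=1.01)
        assert strict["retained"].sum() <= no_r["retained"].sum()
        assert strict["retained"].sum() <= no_p["retained"].sum()


def _clique_pair_graph():
    g = nx.Graph()
    c1 = [f"x{i}" for i in range(5)]
    c2 = [f"y{i}" for i in range(5)]
    g.add_edges_from(itertools.combinations(c1, 2))
    g.add_edges_from(itertools.combinations(c2, 2))
    g.add_edge(c1[0], c2[0])
    return g, set(c1), set(c2)


class TestDetectModules:
    def test_two_cliques_recovered(self):
        g, c1, c2 = _clique_pair_graph()
        modules, rank = detect_modules(g)
        parts = {}
        for node, mod in modules.items():
            parts.setdefault(mod, set()).add(node)
        assert set(map(frozenset, parts.values())) == {frozenset(c1), frozenset(c2)}
        # exhaustive check: returned 2-way partition maximizes modularity
        best = nx.community.modularity(g, [c1, c2])
        nodes = sorted(g.nodes)
        for size in range(1, len(nodes) // 2 + 1):
            for combo in itertools.combinations(nodes, size):
                part = [set(combo), set(nodes) - set(combo)]
                assert nx.community.modularity(g, part) <= best + 1e-12

    def test_complete_graph_single_module(self):
        g = nx.complete_graph(6)
        modules, rank = detect_modules(g)
        assert len(set(modules.values())) == 1
        assert rank == {1: 1}

    def test_louvain_seed_reproducible(self):
        g, _, _ = _clique_pair_graph()
        a = detect_modules(g, algorithm="louvain", seed=3)
        b = detect_modules(g, algorithm="louvain", seed=3)
        assert a == b

    def test_isolated_nodes_become_unranked_singletons(self):
        g, c1, c2 = _clique_pair_graph()
        g.add_node("lonely")
        modules, rank = detect_modules(g)
        assert modules["lonely"] not in rank

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            detect_modules(nx.Graph())


@pytest.fixture(scope="module")
def planted_network(module_truth):
    from strawcue.synthetic import ExperimentDesign, default_truth, generate_asv_tables

    design = ExperimentDesign(timepoints_days=(7,), seed=21)
    truth = default_truth(design, community=module_truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bact, fungi = generate_asv_tables(design, truth)
        net = build_network(bact, fungi, seed=0)
    return net, bact, fungi


class TestModuleStats:
    def test_counts_and_abundances_match_brute_force(self, planted_network):
        net, bact, fungi = planted_network
        counts_df, abund_df = module_stats(net, bact, fungi, top_k=3)
        domains = nx.get_node_attributes(net.graph, "domain")
        props = {
            "bacterial": relative_abundance(bact),
            "fungal": relative_abundance(fungi),
        }
        meta = bact.sample_metadata
        for _, row in counts_df.iterrows():
            members = [n for n, m in net.modules.items() if m == row["module"]]
            assert row["n_bacterial"] == sum(
                1 for n in members if domains[n] == "bacterial"
            )
            assert row["n_fungal"] == sum(1 for n in members if domains[n] == "fungal")
        for _, row in abund_df.iterrows():
            members = [
                n
                for n, m in net.modules.items()
                if m == row["module"] and domains[n] == row["domain"]
            ]
            samples = meta.index[meta["treatment"] == row["treatment"]]
            direct = sum(
                props[row["domain"]].loc[s, m] for s in samples for m in members
            ) / len(samples)
            assert row["mean_rel_abundance"] == pytest.approx(direct, rel=1e-9)

    def test_bacteria_only_module_has_zero_fungal_stats(self, toy_table):
        fungal_counts = toy_table.counts.rename(columns=lambda c: c.replace("asv", "f"))
        fungi = AsvTable(
            fungal_counts,
            pd.DataFrame(
                {"phylum": ["Ascomycota"] * 4},
                index=pd.Index(fungal_counts.columns, name="asv_id"),
            ),
            "fungal",
            toy_table.sample_metadata,
        )
        g = nx.Graph()
        g.add_edge("asv_common", "asv_abundant", r=0.9, p_raw=0.001, p_adj=0.005, sign=1)
        g.add_node("asv_common", domain="bacterial", phylum="Proteobacteria")
        g.add_node("asv_abundant", domain="bacterial", phylum="Proteobacteria")
        from strawcue.network import CoNetwork

        net = CoNetwork(
            g,
            {"asv_common": 1, "asv_abundant": 1},
            {1: 1},
            pd.DataFrame(columns=["i", "j", "r", "p_raw", "p_adj", "sign"]),
        )
        counts_df, abund_df = module_stats(net, toy_table, fungi, top_k=1)
        assert counts_df.iloc[0]["n_fungal"] == 0
        fungal_rows = abund_df[abund_df["domain"] == "fungal"]
        assert (fungal_rows["mean_rel_abundance"] == 0).all()

    def test_top_k_beyond_modules_warns(self, planted_network):
        net, bact, fungi = planted_network
        with pytest.warns(StrawCueWarning):
            counts_df, _ = module_stats(net, bact, fungi, top_k=99)
        assert len(counts_df) == len(net.module_rank)

    def test_sample_abundance_consistent_with_module_stats(self, planted_network):
        net, bact, fungi = planted_network
        per_sample = module_sample_abundance(net, bact, fungi, top_k=2)
        _, abund_df = module_stats(net, bact, fungi, top_k=2)
        meta = bact.sample_metadata
        for mod in net.top_modules(2):
            for trt in meta["treatment"].unique():
                col = per_sample.loc[meta["treatment"] == trt, f"module_{mod}"]
                expected = abund_df[
                    (abund_df["module"] == mod) & (abund_df["treatment"] == trt)
                ]["mean_rel_abundance"].sum()
                assert col.mean() == pytest.approx(expected, rel=1e-9)


class TestSampleSubnetwork:
    def test_full_sample_gives_full_network(self, planted_network):
        net, bact, fungi = planted_network
        sample = bact.counts.index[0]
        # force presence of every network node in this sample
        bact2 = AsvTable(
            bact.counts + 1, bact.taxonomy, "bacterial", bact.sample_metadata
        )
        fungi2 = AsvTable(
            fungi.counts + 1, fungi.taxonomy, "fungal", fungi.sample_metadata
        )
        sub, metrics = sample_subnetwork(net, sample, bact2, fungi2)
        assert metrics["nodes"] == net.n_nodes
        assert metrics["edges"] == net.n_edges

    def test_absent_nodes_give_empty_subgraph(self, planted_network):
        net, bact, fungi = planted_network
        sample = bact.counts.index[0]
        bact0 = AsvTable(
            bact.counts * 0, bact.taxonomy, "bacterial", bact.sample_metadata
        )
        fungi0 = AsvTable(
            fungi.counts * 0, fungi.taxonomy, "fungal", fungi.sample_metadata
        )
        sub, metrics = sample_subnetwork(net, sample, bact0, fungi0)
        assert metrics == {"sample": sample, "nodes": 0, "edges": 0, "mean_degree": 0.0}

    def test_induced_edges_match_brute_force(self, planted_network):
        net, bact, fungi = planted_network
        sample = bact.counts.index[3]
        sub, metrics = sample_subnetwork(net, sample, bact, fungi)
        present = set(bact.counts.columns[bact.counts.loc[sample] > 0]) | set(
            fungi.counts.columns[fungi.counts.loc[sample] > 0]
        )
        expected_edges = {
            frozenset((u, v))
            for u, v in net.graph.edges
            if u in present and v in present
        }
        assert {frozenset(e) for e in sub.edges} == expected_edges


class TestOrderInvariance:
    def test_network_invariant_to_sample_and_asv_order(self, module_truth):
        from strawcue.synthetic import (
            ExperimentDesign,
            default_truth,
            generate_asv_tables,
        )

        design = ExperimentDesign(timepoints_days=(7,), seed=13)
        truth = default_truth(design, community=module_truth)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bact, fungi = generate_asv_tables(design, truth)
            net1 = build_network(bact, fungi, seed=0)
            rng = np.random.default_rng(0)
            s_perm = rng.permutation(bact.counts.index)
            a_perm = rng.permutation(bact.counts.columns)
            bact2 = AsvTable(
                bact.counts.loc[s_perm, a_perm],
                bact.taxonomy,
                "bacterial",
                bact.sample_metadata,
            )
            fungi2 = AsvTable(
                fungi.counts.loc[s_perm],
                fungi.taxonomy,
                "fungal",
                fungi.sample_metadata,
            )
            net2 = build_network(bact2, fungi2, seed=0)
        edges1 = {frozenset((r["i"], r["j"])) for _, r in net1.edges.iterrows()}
        edges2 = {frozenset((r["i"], r["j"])) for _, r in net2.edges.iterrows()}
        assert edges1 == edges2


def test_combine_tables_requires_shared_samples(toy_table):
    other = AsvTable(
        toy_table.counts.iloc[:3],
        toy_table.taxonomy,
        "fungal",
        toy_table.sample_metadata.iloc[:3],
    )
    with pytest.raises(ValueError, match="same samples"):
        combine_domain_tables(toy_table, other)
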