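"""Neuropeptide network assembly, degrees, topology and conservation."""

import numpy as np
import pandas as pd
import pytest

from devatlas import npnet, simulate


def _proximity(classes, bundles, regions, mode="mid"):
    return npnet.build_proximity(
        pd.Series(bundles, index=classes), pd.Series(regions, index=classes), mode
    )


@pytest.fixture()
def small_world():
    classes = ["A", "B", "C", "D"]
    bundles = [0, 0, 1, 2]
    regions = ["head", "head", "head", "tail"]
    expr = pd.DataFrame(
        {
            "A": [1, 0, 1, 1],
            "B": [0, 1, 0, 1],
            "C": [1, 1, 0, 0],
            "D": [0, 1, 1, 0],
        },
        index=["npp0", "gpcr0", "npp1", "gpcr1"],
    )
    return classes, bundles, regions, expr


class TestInteractionsFilter:
    def test_ec50_boundary_inclusive(self):
        tab = pd.DataFrame(
            {"npp_gene": ["n1", "n2"], "gpcr_gene": ["r1", "r2"],
             "ec50_nM": [500.0, 501.0]}
        )
        expr = pd.DataFrame(1, index=["n1", "n2", "r1", "r2"], columns=["A"])
        kept = npnet.filter_interactions(tab, [expr])
        assert list(kept["npp_gene"]) == ["n1"]

    def test_gene_absent_from_one_stage_dropped(self):
        tab = pd.DataFrame(
            {"npp_gene": ["n1"], "gpcr_gene": ["r1"], "ec50_nM": [100.0]}
        )
        stage1 = pd.DataFrame(1, index=["n1", "r1"], columns=["A"])
        stage2 = pd.DataFrame([[1], [0]], index=["n1", "r1"], columns=["A"])
        assert len(npnet.filter_interactions(tab, [stage1, stage2])) == 0
        assert len(npnet.filter_interactions(tab, [stage1])) == 1


class TestProximity:
    def test_short_same_bundle_only(self, small_world):
        classes, bundles, regions, _ = small_world
        prox = _proximity(classes, bundles, regions, "short")
        assert prox.reachable.loc["A", "B"] == 1
        assert prox.reachable.loc["A", "C"] == 0

    def test_mid_same_region(self, small_world):
        classes, bundles, regions, _ = small_world
        prox = _proximity(classes, bundles, regions, "mid")
        assert prox.reachable.loc["A", "C"] == 1  # same region, other bundle
        assert prox.reachable.loc["A", "D"] == 0  # head vs tail

    def test_symmetric_with_unit_diagonal(self, small_world):
        classes, bundles, regions, _ = small_world
        for mode in ("short", "mid"):
            r = _proximity(classes, bundles, regions, mode).reachable.to_numpy()
            assert np.array_equal(r, r.T)
            assert np.all(np.diag(r) == 1)

    def test_short_nested_in_mid_when_bundles_nest(self, small_world):
        classes, bundles, regions, _ = small_world
        short = _proximity(classes, bundles, regions, "short").reachable
        mid = _proximity(classes, bundles, regions, "mid").reachable
        assert np.all(short.to_numpy() <= mid.to_numpy())

    def test_unassigned_class_errors(self):
        with pytest.raises(ValueError, match="assignment"):
            npnet.build_proximity(
                pd.Series([0, np.nan], index=["A", "B"]),
                pd.Series(["head", "head"], index=["A", "B"]), "short",
            )


class TestPairNetwork:
    def test_single_edge_and_masking(self, small_world):
        classes, bundles, regions, expr = small_world
        prox_short = _proximity(classes, bundles, regions, "short")
        lay = npnet.build_pair_network(expr, ("npp0", "gpcr0", 100.0), prox_short)
        # npp0 in {A, C, D}, gpcr0 in {B, C, D}; short range keeps A->B
        assert lay.adjacency.loc["A", "B"] == 1
        assert lay.adjacency.loc["A", "D"] == 0  # unreachable
        # C expresses both: self-edge under the product formula
        assert lay.adjacency.loc["C", "C"] == 1

    def test_no_self_edges_option(self, small_world):
        classes, bundles, regions, expr = small_world
        prox = _proximity(classes, bundles, regions, "mid")
        lay = npnet.build_pair_network(
            expr, ("npp0", "gpcr0", 1.0), prox, allow_self_edges=False
        )
        assert np.all(np.diag(lay.adjacency.to_numpy()) == 0)

    def test_missing_gene_errors(self, small_world):
        classes, bundles, regions, expr = small_world
        prox = _proximity(classes, bundles, regions, "mid")
        with pytest.raises(KeyError, match="ghost"):
            npnet.build_pair_network(expr, ("ghost", "gpcr0", 1.0), prox)

    def test_edges_respect_proximity_mask(self, small_world):
        classes, bundles, regions, expr = small_world
        for mode in ("short", "mid"):
            prox = _proximity(classes, bundles, regions, mode)
            for pair in [("npp0", "gpcr0", 1.0), ("npp1", "gpcr1", 1.0)]:
                lay = npnet.build_pair_network(expr, pair, prox)
                violations = lay.adjacency.to_numpy() * (
                    1 - prox.reachable.to_numpy()
                )
                assert violations.sum() == 0


class TestAggregateDegrees:
    def test_weight_counts_layers(self, small_world):
        classes, bundles, regions, expr = small_world
        prox = _proximity(classes, bundles, regions, "mid")
        lay = npnet.build_pair_network(expr, ("npp0", "gpcr0", 1.0), prox)
        net = npnet.aggregate_network([lay, lay], "L1")
        assert np.array_equal(net.weighted.to_numpy(), 2 * lay.adjacency.to_numpy())

    def test_empty_layer_list_zero_matrix(self):
        net = npnet.aggregate_network([], "L1", classes=["A", "B"])
        assert net.weighted.to_numpy().sum() == 0

    def test_degree_handshake(self, small_world):
        classes, bundles, regions, expr = small_world
        prox = _proximity(classes, bundles, regions, "mid")
        layers = [
            npnet.build_pair_network(expr, ("npp0", "gpcr0", 1.0), prox),
            npnet.build_pair_network(expr, ("npp1", "gpcr1", 1.0), prox),
        ]
        net = npnet.aggregate_network(layers, "L1")
        deg = npnet.degrees(net)
        n_edges = int((net.weighted.to_numpy() > 0).sum())
        assert deg["in_degree"].sum() == n_edges
        assert deg["out_degree"].sum() == n_edges
        assert (deg["degree"] == deg["in_degree"] + deg["out_degree"]).all()

    def test_removing_layer_never_increases_weight(self, small_world):
        classes, bundles, regions, expr = small_world
        prox = _proximity(classes, bundles, regions, "mid")
        layers = [
            npnet.build_pair_network(expr, ("npp0", "gpcr0", 1.0), prox),
            npnet.build_pair_network(expr, ("npp1", "gpcr1", 1.0), prox),
        ]
        full = npnet.aggregate_network(layers, "L1").weighted.to_numpy()
        part = npnet.aggregate_network(layers[:1], "L1").weighted.to_numpy()
        assert np.all(part <= full)


class TestTopology:
    def _expr(self, n_npp, n_gpcr, total=120):
        cols = [f"c{i}" for i in range(total)]
        df = pd.DataFrame(0, index=["npp", "gpcr"], columns=cols)
        df.loc["npp", cols[:n_npp]] = 1
        df.loc["gpcr", cols[:n_gpcr]] = 1
        return df

    @pytest.mark.parametrize(
        "n_npp,n_gpcr,expected",
        [
            (12, 80, "broadcaster"),
            (80, 12, "integrative"),
            (50, 50, "local"),      # boundary <= 50 is restricted
            (51, 51, "pervasive"),
            (50, 51, "broadcaster"),
            (51, 50, "integrative"),
        ],
    )
    def test_classes(self, n_npp, n_gpcr, expected):
        expr = self._expr(n_npp, n_gpcr)
        assert npnet.classify_topology(expr, ("npp", "gpcr")) == expected

    def test_neuron_counting_via_class_sizes(self):
        expr = self._expr(10, 10, total=20)
        sizes = pd.Series(6, index=expr.columns)  # 10 classes x 6 = 60 neurons
        assert npnet.classify_topology(expr, ("npp", "gpcr"), class_sizes=sizes) \
            == "pervasive"


class TestCompareStages:
    def _net(self, expr, pairs, prox, stage):
        layers = [npnet.build_pair_network(expr, p, prox) for p in pairs]
        return npnet.aggregate_network(layers, stage)

    def test_identical_networks_fully_conserved(self, small_world):
        classes, bundles, regions, expr = small_world
        prox = _proximity(classes, bundles, regions, "mid")
        pairs = [("npp0", "gpcr0", 1.0), ("npp1", "gpcr1", 1.0)]
        net = self._net(expr, pairs, prox, "L1")
        tax, summary = npnet.compare_stages(net, net)
        assert (tax["category"] == "conserved_identical").all()
        assert summary["conserved_frac_a"] == 1.0
        assert summary["conserved_frac_b"] == 1.0

    def test_pairset_taxonomy(self):
        classes = ["A", "B"]
        prox = _proximity(classes, [0, 0], ["head", "head"], "short")

        def layer(npp, gpcr):
            expr = pd.DataFrame(
                {"A": [1, 0], "B": [0, 1]}, index=[npp, gpcr]
            )
            return npnet.build_pair_network(expr, (npp, gpcr, 1.0), prox)

        net_a = npnet.aggregate_network([layer("P1", "R1"), layer("P2", "R2")], "a")
        net_b = npnet.aggregate_network([layer("P2", "R2"), layer("P3", "R3")], "b")
        tax, _ = npnet.compare_stages(net_a, net_b)
        assert tax.loc[0, "category"] == "conserved_shared"
        net_c = npnet.aggregate_network([layer("P3", "R3")], "c")
        net_d = npnet.aggregate_network([layer("P1", "R1")], "d")
        tax2, _ = npnet.compare_stages(net_c, net_d)
        assert tax2.loc[0, "category"] == "conserved_different"

    def test_taxonomy_partitions_edge_union(self, small_world):
        classes, bundles, regions, expr = small_world
        prox = _proximity(classes, bundles, regions, "mid")
        net_a = self._net(expr, [("npp0", "gpcr0", 1.0)], prox, "a")
        net_b = self._net(expr, [("npp1", "gpcr1", 1.0)], prox, "b")
        tax, summary = npnet.compare_stages(net_a, net_b)
        edges_a = set(zip(*np.nonzero(net_a.weighted.to_numpy())))
        edges_b = set(zip(*np.nonzero(net_b.weighted.to_numpy())))
        assert len(tax) == len(edges_a | edges_b)
        assert sum(summary["counts"].values()) == len(edges_a | edges_b)

    def test_conservation_decreases_with_pair_swap_probability(self):
        # stages derived from a shared backbone diverge monotonically as the
        # swap probability grows
        classes = [f"c{i}" for i in range(12)]
        prox = _proximity(classes, [0] * 12, ["head"] * 12, "short")
        rng = np.random.default_rng(0)
        genes = [f"npp{i}" for i in range(6)] + [f"gpcr{i}" for i in range(6)]
        base = pd.DataFrame(
            rng.integers(0, 2, (12, 12)), index=genes, columns=classes
        )
        pairs = [(f"npp{i}", f"gpcr{i}", 1.0) for i in range(6)]

        def swapped(q, seed):
            r = np.random.default_rng(seed)
            expr = base.copy()
            flip = r.random(expr.shape) < q
            expr = expr.where(~flip, 1 - expr)
            layers = [npnet.build_pair_network(expr, p, prox) for p in pairs]
            return npnet.aggregate_network(layers, f"q{q}")

        ref = swapped(0.0, 1)
        fracs = []
        for q in (0.0, 0.2, 0.5):
            _, summary = npnet.compare_stages(ref, swapped(q, 2))
            fracs.append(summary["conserved_frac_a"])
        assert fracs[0] == 1.0
        assert fracs[0] >= fracs[1] >= fracs[2]


def test_graphml_roundtrip(tmp_path, small_world):
    import networkx as nx

    classes, bundles, regions, expr = small_world
    prox = _proximity(classes, bundles, regions, "mid")
    lay = npnet.build_pair_network(expr, ("npp0", "gpcr0", 1.0), prox)
    net = npnet.aggregate_network([lay], "L1")
    path = tmp_path / "net.graphml"
    npnet.to_graphml(net, str(path))
    g = nx.read_graphml(path)
    assert g.number_of_edges() == int((net.weighted.to_numpy() > 0).sum())
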