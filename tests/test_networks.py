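import numpy as np
import pandas as pd
import pytest

from microstab.networks import (
    BipartiteNetwork,
    build_network,
    dn_rewiring,
    network_overlap,
    pairwise_correlation,
)


def net(edges, types=None):
    node_types = {}
    e = {}
    for a, b, *w in edges:
        node_types[a] = (types or {}).get(a, "microbe" if a[0] == "m" else "metabolite")
        node_types[b] = (types or {}).get(b, "microbe" if b[0] == "m" else "metabolite")
        e[frozenset((a, b))] = w[0] if w else 1.0
    return BipartiteNetwork(node_types, e)


class TestPairwiseCorrelation:
    def test_affine_relation_gives_one(self, rng):
        x = pd.DataFrame([rng.normal(0, 1, 20)], index=["m1"], columns=[f"s{i}" for i in range(20)])
        y = pd.DataFrame(2 * x.to_numpy() + 3, index=["t1"], columns=x.columns)
        out = pairwise_correlation(x, y)
        assert out.loc["m1", "t1"] == pytest.approx(1.0)

    def test_independent_rows_mostly_small(self, rng):
        n = 500
        x = pd.DataFrame(rng.normal(0, 1, (10, n)), index=[f"m{i}" for i in range(10)],
                         columns=[f"s{i}" for i in range(n)])
        y = pd.DataFrame(rng.normal(0, 1, (10, n)), index=[f"t{i}" for i in range(10)],
                         columns=x.columns)
        out = pairwise_correlation(x, y).to_numpy()
        assert (np.abs(out) < 0.15).mean() >= 0.99

    def test_partial_correlation_removes_chain_link(self, rng):
        # X -> Y -> Z: partial corr(X,Z | Y) ~ 0 while plain corr(X,Z) large
        n = 400
        x = rng.normal(0, 1, n)
        y = x + 0.3 * rng.normal(0, 1, n)
        z = y + 0.3 * rng.normal(0, 1, n)
        X = pd.DataFrame([x], index=["mX"], columns=[f"s{i}" for i in range(n)])
        Y = pd.DataFrame([y, z], index=["tY", "tZ"], columns=X.columns)
        plain = pairwise_correlation(X, Y, "pearson")
        partial = pairwise_correlation(X, Y, "shrinkage_partial")
        assert plain.loc["mX", "tZ"] > 0.8
        assert abs(partial.loc["mX", "tZ"]) < 0.25
        assert partial.loc["mX", "tY"] > 0.5

    def test_constant_row_flagged_nan(self, rng):
        x = pd.DataFrame([[1.0] * 10, list(rng.normal(0, 1, 10))], index=["m0", "m1"],
                         columns=[f"s{i}" for i in range(10)])
        y = pd.DataFrame([rng.normal(0, 1, 10)], index=["t0"], columns=x.columns)
        out = pairwise_correlation(x, y)
        assert np.isnan(out.loc["m0", "t0"])
        assert out.attrs["constant"]["microbes"] == ["m0"]

    def test_too_few_samples(self):
        x = pd.DataFrame([[1.0, 2, 3]], index=["m"], columns=list("abc"))
        with pytest.raises(ValueError, match="4"):
            pairwise_correlation(x, x.rename(index={"m": "t"}))


class TestBuildNetwork:
    def test_threshold_application(self):
        coeffs = pd.DataFrame(
            [[0.9, 0.5, -0.8]], index=["m1"], columns=["t1", "t2", "t3"]
        )
        n = build_network(coeffs, 0.75)
        assert n.edge_set == {frozenset(("m1", "t1")), frozenset(("m1", "t3"))}
        assert n.node_types == {"m1": "microbe", "t1": "metabolite", "t3": "metabolite"}

    def test_boundary_inclusive(self):
        coeffs = pd.DataFrame([[0.75]], index=["m1"], columns=["t1"])
        assert len(build_network(coeffs, 0.75).edges) == 1

    def test_subthreshold_empty(self):
        coeffs = pd.DataFrame([[0.5, -0.6]], index=["m1"], columns=["t1", "t2"])
        n = build_network(coeffs, 0.75)
        assert not n.edges and not n.nodes

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            build_network(pd.DataFrame([[0.9]], index=["m"], columns=["t"]), 0.0)


class TestOverlap:
    def test_identical_networks(self):
        a = net([("m1", "t1", 0.9), ("m2", "t1", -0.8)])
        rep = network_overlap(a, a)
        assert rep.shared_node_fraction == 1.0
        assert rep.shared_edge_fraction == 1.0
        assert rep.rewired_fraction == 0.0

    def test_disjoint_networks(self):
        a = net([("m1", "t1")])
        b = net([("m2", "t2")])
        rep = network_overlap(a, b)
        assert rep.shared_node_fraction == 0.0
        assert rep.rewired_fraction == 1.0

    def test_worked_set_arithmetic(self):
        # V1={a,b,c}, E1={ab,bc}; V2={b,c,d}, E2={bc,cd}
        a = net([("a", "b"), ("b", "c")], types={"a": "microbe", "b": "metabolite", "c": "microbe"})
        b = net([("b", "c"), ("c", "d")], types={"b": "metabolite", "c": "microbe", "d": "metabolite"})
        rep = network_overlap(a, b)
        assert rep.shared_node_fraction == pytest.approx(0.5)
        assert rep.shared_edge_fraction == pytest.approx(1 / 3)

    def test_symmetry(self, rng):
        a = net([("m1", "t1"), ("m2", "t2")])
        b = net([("m1", "t2")])
        ra, rb = network_overlap(a, b), network_overlap(b, a)
        assert ra.shared_node_fraction == rb.shared_node_fraction
        assert ra.shared_edge_fraction == rb.shared_edge_fraction

    def test_both_empty_errors(self):
        with pytest.raises(ValueError):
            network_overlap(net([]), net([]))


def brute_force_dn(a: BipartiteNetwork, b: BipartiteNetwork, node: str) -> float:
    """Direct evaluation of ||a1 - c|| + ||a2 - c|| over the union node set."""
    union = sorted(a.nodes | b.nodes)
    a1 = np.array([1.0 if frozenset((node, u)) in a.edges else 0.0 for u in union])
    a2 = np.array([1.0 if frozenset((node, u)) in b.edges else 0.0 for u in union])
    c = (a1 + a2) / 2
    return float(np.linalg.norm(a1 - c) + np.linalg.norm(a2 - c))


class TestDnRewiring:
    def test_identical_neighborhood_zero(self):
        a = net([("m1", "t1"), ("m1", "t2")])
        dn = dn_rewiring(a, a)
        assert (dn["dn"] == 0).all()

    def test_single_edge_lost(self):
        a = net([("m1", "t1")])
        b = BipartiteNetwork({"m1": "microbe", "t1": "metabolite"}, {})
        dn = dn_rewiring(a, b)
        assert dn.loc["m1", "dn"] == pytest.approx(1.0)
        assert dn.loc["m1", "degree_corrected_dn"] == pytest.approx(1.0)

    @pytest.mark.parametrize("k1,k2", [(1, 0), (2, 3), (5, 5), (0, 4)])
    def test_closed_form_disjoint_neighborhoods(self, k1, k2):
        a = net([("m0", f"t{i}") for i in range(k1)] or [("x1", "x2")])
        b = net([("m0", f"u{i}") for i in range(k2)] or [("x1", "x2")])
        if k1 == 0:
            a.node_types["m0"] = "microbe"
        if k2 == 0:
            b.node_types["m0"] = "microbe"
        dn = dn_rewiring(a, b)
        assert dn.loc["m0", "dn"] == pytest.approx(np.sqrt(k1 + k2))
        assert dn.loc["m0", "degree_corrected_dn"] == pytest.approx(1 / np.sqrt(k1 + k2))
        assert dn.loc["m0", "dn"] == pytest.approx(brute_force_dn(a, b, "m0"))

    def test_matches_brute_force_on_small_graphs(self, rng):
        nodes = ["m1", "m2", "t1", "t2", "t3"]
        pairs = [(m, t) for m in ("m1", "m2") for t in ("t1", "t2", "t3")]
        for trial in range(20):
            r = np.random.default_rng(trial)
            e1 = [p for p in pairs if r.random() < 0.5]
            e2 = [p for p in pairs if r.random() < 0.5]
            if not e1 or not e2:
                continue
            a, b = net(e1), net(e2)
            dn = dn_rewiring(a, b)
            for node in dn.index:
                assert dn.loc[node, "dn"] == pytest.approx(brute_force_dn(a, b, node))

    def test_state_order_symmetry(self):
        a = net([("m1", "t1"), ("m2", "t2")])
        b = net([("m1", "t2")])
        pd.testing.assert_frame_equal(dn_rewiring(a, b), dn_rewiring(b, a))

    def test_absent_node_errors_without_flag(self):
        a = net([("m1", "t1")])
        with pytest.raises(ValueError, match="absent"):
            dn_rewiring(a, a, nodes=["zz"])
        dn = dn_rewiring(a, a, nodes=["zz"], allow_absent=True)
        assert dn.loc["zz", "dn"] == 0.0


class TestPlantedCouplingRecovery:
    def test_planted_metabolites_rewire_more(self, small_trial):
        import scipy.stats

        from microstab.compositional import clr_transform, normalize_metabolites

        clr = clr_transform(small_trial.asv_table)
        norm = normalize_metabolites(small_trial.metabolite_table, small_trial.metadata)
        nets = {}
        for g in ("placebo", "treatment"):
            cols = [s for s in clr.columns if small_trial.metadata.group_of(s) == g]
            nets[g] = build_network(pairwise_correlation(clr[cols], norm[cols]), 0.75)
        planted = {p[1] for p in small_trial.truth["coupled_pairs"]}
        dn = dn_rewiring(
            nets["placebo"],
            nets["treatment"],
            nodes=small_trial.metabolite_table.feature_ids,
            allow_absent=True,
        )
        a = dn.loc[sorted(planted), "degree_corrected_dn"]
        b = dn.drop(sorted(planted))["degree_corrected_dn"]
        p = scipy.stats.mannwhitneyu(a, b, alternative="greater").pvalue
        assert a.mean() > b.mean()
        assert p < 0.05
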