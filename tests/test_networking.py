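"""Molecular network construction, clustering, propagation, distributions."""

import numpy as np
import pytest

from pyrosom.alignment import AlignedFeature
from pyrosom.annotation import UNCLASSIFIED, Annotation
from pyrosom.deconvolution import Feature
from pyrosom.errors import ParameterError
from pyrosom.networking import (
    _mutual_topk_edges,
    build_network,
    clusters,
    ecosystem_distribution,
    propagate_classes,
    write_edge_list,
    write_graphml,
)
from pyrosom.similarity import cosine_matrix
from pyrosom.spectra_io import Spectrum
from pyrosom.synthetic import gen_compound

from conftest import make_spectrum


def node(spec, node_id, heights=None):
    heights = heights or {"s1": 1e6}
    member = Feature(rt=1.0, spectrum=spec, height=max(heights.values()),
                     area=0.0, sample_id=sorted(heights)[0])
    return AlignedFeature(node_id=node_id, members=[member],
                          consensus_spectrum=spec, rt=1.0,
                          per_sample_height=dict(heights))


def ann(node_id, compound=None, cls=UNCLASSIFIED, score=0.0):
    return Annotation(node_id=node_id, compound=compound, score=score,
                      compound_class=cls)


def random_spectra(n, seed, n_mz=(3, 20), mz_range=(29, 400)):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        k = int(rng.integers(*n_mz))
        mz = np.sort(rng.choice(np.arange(*mz_range), k, replace=False))
        out.append(Spectrum(mz.astype(float), rng.uniform(1, 999, k)))
    return out


def brute_force_mutual_topk(sim, min_cosine, topk):
    """Independent O(n^2) oracle for the pruning rule."""
    n = sim.shape[0]
    edges = set()
    tops = []
    for i in range(n):
        cand = [(sim[i, j], j) for j in range(n)
                if j != i and sim[i, j] >= min_cosine]
        cand.sort(key=lambda t: (-t[0], t[1]))
        tops.append({j for _, j in cand[:topk]})
    for i in range(n):
        for j in range(i + 1, n):
            if j in tops[i] and i in tops[j]:
                edges.add((i, j))
    return edges


class TestBuildNetwork:
    def test_three_identical_spectra_form_triangle(self):
        s = make_spectrum({91: 999, 65: 110})
        nodes = [node(s, f"n{i}") for i in range(3)]
        net = build_network(nodes, [ann(f"n{i}") for i in range(3)])
        assert len(net.edges) == 3
        assert all(c == pytest.approx(1.0) for _, _, c in net.edges)

    def test_subthreshold_pair_stays_singleton(self):
        # cosine ~0.447 < 0.7
        a = node(make_spectrum({50: 100}), "a")
        b = node(make_spectrum({50: 50, 77: 100}), "b")
        net = build_network([a, b], [ann("a"), ann("b")])
        assert net.edges == []
        assert net.singletons == {"a", "b"}
        assert clusters(net) == []

    def test_fifteen_near_identical_nodes_match_oracle(self):
        rng = np.random.default_rng(8)
        base = make_spectrum({91: 999, 65: 110, 39: 120, 51: 45})
        nodes = []
        for i in range(15):
            jitter = base.intensity * rng.lognormal(0.0, 0.02, len(base))
            nodes.append(node(Spectrum(base.mz, jitter), f"n{i:02d}"))
        net = build_network(nodes, [ann(n.node_id) for n in nodes],
                            min_cosine=0.7, topk=10)
        sim = cosine_matrix([n.consensus_spectrum for n in nodes])
        oracle = brute_force_mutual_topk(sim, 0.7, 10)
        got = {(int(a[1:]), int(b[1:])) for a, b, _ in net.edges}
        got = {(min(e), max(e)) for e in got}
        assert got == oracle
        assert all(net.degree(n.node_id) <= 10 for n in nodes)

    def test_mutual_topk_oracle_on_random_sets(self):
        for seed in (1, 2, 3):
            specs = random_spectra(40, seed)
            sim = cosine_matrix(specs)
            edges = _mutual_topk_edges([f"{i:02d}" for i in range(40)],
                                       sim, 0.5, 4)
            got = {(int(a), int(b)) for a, b, _ in edges}
            assert got == brute_force_mutual_topk(sim, 0.5, 4)

    def test_degree_bound_and_edge_validity(self):
        specs = random_spectra(60, seed=99, n_mz=(3, 8), mz_range=(29, 60))
        nodes = [node(s, f"n{i:02d}") for i, s in enumerate(specs)]
        net = build_network(nodes, [ann(n.node_id) for n in nodes],
                            min_cosine=0.6, topk=3)
        assert all(net.degree(n.node_id) <= 3 for n in nodes)
        if net.edges:
            assert min(c for _, _, c in net.edges) >= 0.6

    def test_fewer_than_two_nodes_empty_network(self):
        s = make_spectrum({91: 999})
        net = build_network([node(s, "only")], [ann("only")])
        assert net.edges == []

    def test_parameter_preconditions(self):
        with pytest.raises(ParameterError):
            build_network([], [], min_cosine=0)
        with pytest.raises(ParameterError):
            build_network([], [], topk=0)


class TestClusters:
    def test_two_disjoint_triangles(self):
        s1 = make_spectrum({91: 999, 65: 110})
        s2 = make_spectrum({219: 999, 180: 400})
        nodes = [node(s1, f"a{i}") for i in range(3)]
        nodes += [node(s2, f"b{i}") for i in range(3)]
        net = build_network(nodes, [ann(n.node_id) for n in nodes])
        comps = clusters(net)
        assert sorted(map(len, comps)) == [3, 3]
        assert {frozenset(c) for c in comps} == {
            frozenset({"a0", "a1", "a2"}), frozenset({"b0", "b1", "b2"})}

    def test_components_match_union_find_oracle(self):
        specs = random_spectra(50, seed=13)
        nodes = [node(s, f"n{i:02d}") for i, s in enumerate(specs)]
        net = build_network(nodes, [ann(n.node_id) for n in nodes],
                            min_cosine=0.4, topk=5)
        # union-find oracle over the pruned edge list
        parent = {n.node_id: n.node_id for n in nodes}
        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x
        for a, b, _ in net.edges:
            parent[find(a)] = find(b)
        expected = {}
        connected = {n for a, b, _ in net.edges for n in (a, b)}
        for nid in connected:
            expected.setdefault(find(nid), set()).add(nid)
        assert {frozenset(c) for c in clusters(net)} == {
            frozenset(c) for c in expected.values()}


class TestPropagation:
    def _pair_net(self):
        s1 = make_spectrum({91: 999, 65: 110, 39: 120})
        s2 = make_spectrum({91: 900, 65: 140, 39: 100})
        nodes = [node(s1, "known"), node(s2, "mystery")]
        anns = [ann("known", compound="Guaiacol", cls="lignin", score=0.9),
                ann("mystery")]
        return build_network(nodes, anns)

    def test_unclassified_node_takes_neighbor_class(self):
        net = propagate_classes(self._pair_net())
        assert net.classes["mystery"] == "lignin"
        assert net.provenance["mystery"] == "propagated"
        assert net.provenance["known"] == "library"

    def test_isolated_unclassified_cluster_unchanged(self):
        s = make_spectrum({91: 999, 65: 110})
        nodes = [node(s, "x"), node(s, "y")]
        net = build_network(nodes, [ann("x"), ann("y")])
        after = propagate_classes(net)
        assert after.classes == {"x": UNCLASSIFIED, "y": UNCLASSIFIED}

    def test_monotone_and_label_invariance(self):
        net = self._pair_net()
        after = propagate_classes(net)
        before_unc = sum(1 for c in net.classes.values() if c == UNCLASSIFIED)
        after_unc = sum(1 for c in after.classes.values() if c == UNCLASSIFIED)
        assert after_unc <= before_unc
        assert after.classes["known"] == "lignin"

    def test_hidden_label_recovery(self):
        """Hiding half the labels in a 3-family network: >= 90% recovered."""
        rng = np.random.default_rng(42)
        nodes, anns, truth = [], [], {}
        k = 0
        for fam, cls in (("famL", "lignin"), ("famP", "phenols"),
                         ("famM", "MAH")):
            for _ in range(20):
                c = gen_compound(int(rng.integers(0, 2**31 - 1)), fam,
                                 compound_class=cls)
                nid = f"n{k:02d}"
                nodes.append(node(c.spectrum, nid))
                truth[nid] = cls
                k += 1
        hidden = set(rng.choice([n.node_id for n in nodes], size=30,
                                replace=False))
        for n in nodes:
            if n.node_id in hidden:
                anns.append(ann(n.node_id))
            else:
                anns.append(ann(n.node_id, compound=n.node_id,
                                cls=truth[n.node_id], score=0.9))
        net = build_network(nodes, anns, min_cosine=0.7, topk=10)
        after = propagate_classes(net)
        recovered = [nid for nid in hidden
                     if after.classes[nid] != UNCLASSIFIED]
        correct = sum(1 for nid in recovered
                      if after.classes[nid] == truth[nid])
        assert len(recovered) > 0
        assert correct / len(recovered) >= 0.9
        before_unc = sum(1 for c in net.classes.values() if c == UNCLASSIFIED)
        after_unc = sum(1 for c in after.classes.values() if c == UNCLASSIFIED)
        assert after_unc < before_unc
        for nid, cls in truth.items():
            if nid not in hidden:
                assert after.classes[nid] == cls


class TestEcosystemDistribution:
    def test_shares_normalize_and_wetland_only(self):
        s = make_spectrum({91: 999})
        n1 = node(s, "wet", heights={"vernal_pool": 3.0, "prairie_pothole": 1.0,
                                     "forest": 0.0})
        n2 = node(s, "everywhere", heights={"vernal_pool": 1.0,
                                            "prairie_pothole": 1.0,
                                            "forest": 2.0})
        net = build_network([n1, n2], [ann("wet"), ann("everywhere")])
        dist = ecosystem_distribution(net)
        assert dist.shares.loc["wet", "vernal_pool"] == pytest.approx(0.75)
        assert dist.shares.loc["wet", "forest"] == 0.0
        assert np.allclose(dist.shares.sum(axis=1), 1.0)
        assert dist.exclusive_nodes(["vernal_pool", "prairie_pothole"]) == ["wet"]
        assert dist.presence_counts == {2: 1, 3: 1}

    def test_zero_abundance_node_flagged(self):
        s = make_spectrum({91: 999})
        n1 = node(s, "zero", heights={"s1": 0.0})
        n2 = node(s, "ok", heights={"s1": 5.0})
        net = build_network([n1, n2], [ann("zero"), ann("ok")])
        dist = ecosystem_distribution(net)
        assert dist.zero_abundance_nodes == ["zero"]
        assert "zero" not in dist.shares.index

    def test_shares_match_row_normalization_oracle(self, rng):
        s = make_spectrum({91: 999})
        heights = {f"e{j}": float(h)
                   for j, h in enumerate(rng.uniform(0, 10, size=5))}
        net = build_network([node(s, "n0", heights=heights),
                             node(s, "n1", heights=heights)],
                            [ann("n0"), ann("n1")])
        dist = ecosystem_distribution(net)
        total = sum(heights.values())
        for eco, h in heights.items():
            assert dist.shares.loc["n0", eco] == pytest.approx(h / total)


def test_exports_are_readable(tmp_path):
    s1 = make_spectrum({91: 999, 65: 110})
    nodes = [node(s1, f"n{i}") for i in range(3)]
    net = build_network(nodes, [ann("n0", compound="Toluene", cls="MAH",
                                    score=1.0), ann("n1"), ann("n2")])
    net = propagate_classes(net)
    edge_path = tmp_path / "edges.tsv"
    write_edge_list(net, edge_path)
    lines = edge_path.read_text().strip().splitlines()
    assert lines[0] == "node_a\tnode_b\tcosine"
    assert len(lines) == 1 + len(net.edges)
    import networkx as nx
    gml = tmp_path / "net.graphml"
    write_graphml(net, gml)
    g = nx.read_graphml(gml)
    assert g.nodes["n1"]["compound_class"] == "MAH"
    assert g.nodes["n1"]["provenance"] == "propagated"
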