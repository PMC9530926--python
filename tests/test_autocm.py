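"""Auto contractive map, MST projection and Spin Net equilibrium queries."""

import heapq
import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from otomir.autocm import (
    AutoCMModel,
    ScaledDataset,
    export_graph,
    import_graphml,
    minimum_spanning_tree,
    scale_with_complements,
    spinnet_query,
    train_autocm,
    weights_to_distances,
)


def brute_force_mst_total(d: np.ndarray) -> float:
    """Exhaustive minimum over all labeled spanning trees (Pruefer decode)."""
    n = d.shape[0]
    if n == 1:
        return 0.0
    if n == 2:
        return float(d[0, 1])
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        deg = [1] * n
        for s in seq:
            deg[s] += 1
        total = 0.0
        leaves = [i for i in range(n) if deg[i] == 1]
        heapq.heapify(leaves)
        for s in seq:
            leaf = heapq.heappop(leaves)
            total += d[leaf, s]
            deg[s] -= 1
            if deg[s] == 1:
                heapq.heappush(leaves, s)
        u, v = heapq.heappop(leaves), heapq.heappop(leaves)
        total += d[u, v]
        best = min(best, total)
    return float(best)


def _model_from_w(w: np.ndarray, C: float, names=None) -> AutoCMModel:
    names = names or [f"v{i}" for i in range(w.shape[0])]
    return AutoCMModel(
        C=C,
        v=pd.Series(np.zeros(len(names)), index=names),
        W=pd.DataFrame(w, index=names, columns=names),
        epochs_run=1,
        convergence=[0.0],
    )


class TestScaling:
    def test_minmax_and_complement_example(self):
        raw = pd.DataFrame({"x": [0.0, 5.0, 10.0]})
        ds = scale_with_complements(raw)
        assert np.allclose(ds.data["Max_x"], [0.0, 0.5, 1.0])
        assert np.allclose(ds.data["Min_x"], [1.0, 0.5, 0.0])

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30).filter(
            lambda xs: max(xs) > min(xs)
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_complement_sums_to_one(self, xs):
        ds = scale_with_complements(pd.DataFrame({"x": xs}))
        assert np.allclose(ds.data["Max_x"] + ds.data["Min_x"], 1.0)

    def test_constant_column_dropped_with_warning(self):
        raw = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [4.0, 4.0, 4.0]})
        with pytest.warns(UserWarning, match="'c'"):
            ds = scale_with_complements(raw)
        assert "Max_c" not in ds.data.columns

    def test_genotypes_become_indicator_columns(self):
        raw = pd.DataFrame({"hOGG1": ["wt", "het", "mut", "wt"], "x": [0, 1, 2, 3.0]})
        ds = scale_with_complements(raw)
        assert {"Max_hOGG1_wt", "Max_hOGG1_het", "Max_hOGG1_mut"} <= set(ds.data.columns)
        assert ds.provenance["Max_hOGG1_wt"] == "polymorphism"


class TestTraining:
    def test_all_zero_dataset_leaves_weights_at_initialization(self):
        ds = ScaledDataset(pd.DataFrame(np.zeros((10, 4))))
        model = train_autocm(ds, max_epochs=5)
        assert np.allclose(model.v, model.C / 1e6)
        assert np.allclose(model.W, model.C / 1e6)

    def test_duplicated_columns_attain_row_maximal_weight(self, rng):
        base = rng.random((200, 6))
        raw = pd.DataFrame(base, columns=[f"x{i}" for i in range(6)])
        raw["dup"] = raw["x0"]
        model = train_autocm(scale_with_complements(raw), max_epochs=40)
        row = model.W.loc["Max_x0"].drop(["Max_x0", "Min_x0"])
        assert row.idxmax() == "Max_dup"

    def test_training_is_deterministic(self, rng):
        raw = pd.DataFrame(rng.random((40, 4)))
        raw.columns = [f"x{i}" for i in range(4)]
        ds = scale_with_complements(raw)
        m1 = train_autocm(ds, max_epochs=20)
        m2 = train_autocm(ds, max_epochs=20)
        assert m1.W.equals(m2.W) and m1.v.equals(m2.v)

    def test_weights_bounded_and_monotone(self, rng):
        for _ in range(5):
            raw = pd.DataFrame(rng.random((30, 3)), columns=list("abc"))
            ds = scale_with_complements(raw)
            M = ds.data.to_numpy()
            C = float(len(M))
            prev_w = None
            model = None
            for epochs in (1, 3, 6, 10):
                model = train_autocm(ds, C=C, max_epochs=epochs, tol=0.0)
                w = model.W.to_numpy()
                assert (w >= 0).all() and (w < C).all()
                if prev_w is not None:
                    assert (w >= prev_w - 1e-12).all()  # contractive growth
                prev_w = w
            conv = np.array(model.convergence)
            assert np.all(np.diff(conv[2:]) <= 1e-10)

    def test_out_of_range_data_rejected(self):
        with pytest.raises(ValueError):
            ScaledDataset(pd.DataFrame([[0.5, 1.5]]))


class TestDistances:
    def test_definition_and_symmetry(self, rng):
        w = rng.random((5, 5)) * 3
        model = _model_from_w(w, C=10.0)
        d = weights_to_distances(model).to_numpy()
        wbar = (w + w.T) / 2
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(d[off], (1 - wbar / 10.0)[off])
        assert np.allclose(d, d.T)
        # monotone: larger symmetrized weight means smaller distance
        i, j = np.unravel_index(np.argmax(wbar + np.where(off, 0, -np.inf)), wbar.shape)
        assert d[i, j] == d[off].min()


class TestMst:
    def test_four_vertex_example(self):
        names = list("ABCD")
        d = np.array(
            [[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6], [3, 5, 6, 0]], dtype=float
        )
        g = minimum_spanning_tree(pd.DataFrame(d, index=names, columns=names))
        assert {frozenset(e[:2]) for e in g.mst_edges} == {
            frozenset("AB"), frozenset("AC"), frozenset("AD"),
        }
        assert sum(e[2] for e in g.mst_edges) == 6.0

    def test_edge_count_and_spanning(self, rng):
        n = 9
        a = rng.random((n, n))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0)
        names = [f"v{i}" for i in range(n)]
        g = minimum_spanning_tree(pd.DataFrame(d, index=names, columns=names))
        assert len(g.mst_edges) == n - 1
        assert nx.is_connected(g.mst) and g.mst.number_of_nodes() == n

    def test_label_permutation_equivariance(self, rng):
        n = 6
        a = rng.random((n, n))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0)
        names = [f"v{i}" for i in range(n)]
        g1 = minimum_spanning_tree(pd.DataFrame(d, index=names, columns=names))
        perm = rng.permutation(n)
        pnames = [names[i] for i in perm]
        dp = d[np.ix_(perm, perm)]
        g2 = minimum_spanning_tree(pd.DataFrame(dp, index=pnames, columns=pnames))
        assert {frozenset(e[:2]) for e in g1.mst_edges} == {
            frozenset(e[:2]) for e in g2.mst_edges
        }

    def test_matches_brute_force_on_small_graphs(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 7))
            a = rng.random((n, n))
            d = (a + a.T) / 2
            np.fill_diagonal(d, 0)
            names = [f"v{i}" for i in range(n)]
            g = minimum_spanning_tree(pd.DataFrame(d, index=names, columns=names))
            assert sum(e[2] for e in g.mst_edges) == pytest.approx(
                brute_force_mst_total(d)
            )


class TestSpinNet:
    def test_two_node_closed_form(self):
        model = _model_from_w(np.array([[0.0, 5.0], [5.0, 0.0]]), C=10.0, names=["A", "B"])
        table, cycles = spinnet_query(model, ["A"], damping=0.9)
        act = table.set_index("variable")["activation"]
        assert act["B"] == pytest.approx(0.9, abs=1e-9)
        assert act["A"] == 1.0

    def test_clamped_variable_ranked_first(self, rng):
        w = rng.random((8, 8)) * 2
        model = _model_from_w(w, C=10.0)
        table, _ = spinnet_query(model, ["v3"])
        assert table.iloc[0]["variable"] == "v3"
        assert ((table["activation"] >= 0) & (table["activation"] <= 1)).all()

    def test_differences_decay_geometrically(self, rng):
        w = rng.random((6, 6)) * 2
        model = _model_from_w(w, C=10.0)
        names = model.variables
        W = model.W.to_numpy()
        wbar = (W + W.T) / 2
        np.fill_diagonal(wbar, 0)
        wt = wbar / wbar.sum(axis=1, keepdims=True)
        damping = 0.9
        a = np.zeros(6)
        a[0] = 1.0
        diffs = []
        for _ in range(20):
            new = damping * (a @ wt)
            new[0] = 1.0
            diffs.append(np.max(np.abs(new - a)))
            a = new
        diffs = np.array(diffs[1:])
        assert np.all(diffs[1:] <= damping * diffs[:-1] + 1e-12)

    def test_validation(self, rng):
        model = _model_from_w(rng.random((4, 4)), C=5.0)
        with pytest.raises(ValueError):
            spinnet_query(model, [])
        with pytest.raises(KeyError):
            spinnet_query(model, ["nope"])
        with pytest.raises(ValueError):
            spinnet_query(model, ["v0"], damping=1.0)

    def test_mst_neighbours_rank_high_in_planted_structure(self, rng):
        # two tight variable clusters: clamping a member of one cluster
        # must activate its own cluster above the other
        n = 120
        z1, z2 = rng.random(n), rng.random(n)
        raw = pd.DataFrame(
            {
                "a1": z1 + rng.normal(0, 0.05, n),
                "a2": z1 + rng.normal(0, 0.05, n),
                "a3": z1 + rng.normal(0, 0.05, n),
                "b1": z2 + rng.normal(0, 0.05, n),
                "b2": z2 + rng.normal(0, 0.05, n),
                "b3": z2 + rng.normal(0, 0.05, n),
            }
        )
        model = train_autocm(scale_with_complements(raw), max_epochs=40)
        table, _ = spinnet_query(model, ["Max_a1"])
        act = table.set_index("variable")["activation"]
        assert min(act["Max_a2"], act["Max_a3"]) > max(act["Max_b1"], act["Max_b2"])


class TestExport:
    def test_graphml_round_trip(self, rng, tmp_path):
        n = 5
        a = rng.random((n, n))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0)
        names = [f"Max_x{i}" for i in range(n)]
        g = minimum_spanning_tree(pd.DataFrame(d, index=names, columns=names))
        ann = {v: {"provenance": "microRNA"} for v in names}
        graphml, dot = export_graph(g.mst, tmp_path, annotations=ann)
        back = import_graphml(graphml)
        assert nx.is_isomorphic(g.mst, back)
        assert set(back.nodes) == set(names)
        assert back.nodes[names[0]]["provenance"] == "microRNA"
        assert back.nodes[names[0]]["polarity"] == "Max"
        for u, v, data in back.edges(data=True):
            assert g.mst[u][v]["distance"] == pytest.approx(data["distance"])
        assert "graph {" in open(dot).read()

    def test_empty_graph_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_graph(nx.Graph(), tmp_path)

    def test_duplicate_vertex_labels_rejected(self, rng):
        d = rng.random((3, 3))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        frame = pd.DataFrame(d, index=["a", "a", "b"], columns=["a", "a", "b"])
        with pytest.raises(ValueError, match="a"):
            minimum_spanning_tree(frame)
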