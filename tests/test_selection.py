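import itertools

import networkx as nx
import numpy as np
import pytest

import cohortdag as cd
from cohortdag.selection import ThresholdCurve, support_graph


def _binary_dataset(columns: dict[str, np.ndarray], outcome: str) -> cd.Dataset:
    specs = []
    for name in columns:
        specs.append(
            {
                "name": name,
                "scale": "binary",
                "levels": ["0", "1"],
                **({"outcome": True} if name == outcome else {}),
            }
        )
    values = np.column_stack(list(columns.values())).astype(float)
    return cd.Dataset(values, cd.load_specs(specs))


def brute_force_bic(graph: nx.DiGraph, ds: cd.Dataset) -> float:
    """Oracle: enumerate all parent configurations explicitly."""
    df = ds.to_frame()
    N = len(df)
    card = {s.name: s.cardinality for s in ds.specs}
    total = 0.0
    for node in graph.nodes:
        parents = sorted(graph.predecessors(node))
        configs = list(itertools.product(*[range(card[p]) for p in parents])) or [()]
        ll = 0.0
        for cfg in configs:
            mask = np.ones(N, dtype=bool)
            for p, v in zip(parents, cfg):
                mask &= df[p].to_numpy() == v
            n_ij = mask.sum()
            if n_ij == 0:
                continue
            for k in range(card[node]):
                n_ijk = (df[node].to_numpy()[mask] == k).sum()
                if n_ijk > 0:
                    ll += n_ijk * np.log(n_ijk / n_ij)
        dim = (card[node] - 1) * int(np.prod([card[p] for p in parents])) if parents else card[node] - 1
        total += ll - np.log(N) / 2 * dim
    return total


class TestBicScore:
    def test_single_binary_variable_closed_form(self):
        ds = _binary_dataset({"y": np.array([0, 0, 1, 1]), "pad": np.zeros(4)}, "y")
        g = nx.DiGraph()
        g.add_node("y")
        score = cd.bic_score(g, ds)
        # LL = 4 ln(1/2) = -2.77259; dim = 1; penalty = ln(4)/2
        assert score == pytest.approx(4 * np.log(0.5) - np.log(4) / 2, abs=1e-9)
        assert score == pytest.approx(-3.46574, abs=1e-5)

    def test_empty_graph_decomposes_into_singletons(self):
        rng = np.random.default_rng(0)
        cols = {f"v{i}": rng.integers(0, 2, 100) for i in range(4)}
        cols["y"] = rng.integers(0, 2, 100)
        ds = _binary_dataset(cols, "y")
        g_all = nx.DiGraph()
        g_all.add_nodes_from(cols)
        total = sum(cd.bic_score(_singleton(n), ds) for n in cols)
        assert cd.bic_score(g_all, ds) == pytest.approx(total, abs=1e-9)

    def test_independent_variables_prefer_empty_graph(self):
        rng = np.random.default_rng(33)
        ds = _binary_dataset(
            {"a": rng.integers(0, 2, 2000), "b": rng.integers(0, 2, 2000)}, "b"
        )
        empty = nx.DiGraph()
        empty.add_nodes_from(["a", "b"])
        edge = nx.DiGraph([("a", "b")])
        assert cd.bic_score(empty, ds) > cd.bic_score(edge, ds)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_brute_force_contingency_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        a = rng.integers(0, 2, n)
        b = (a + rng.integers(0, 2, n)) % 2
        c = rng.integers(0, 3, n)
        y = ((b + c) > 2).astype(int)
        specs = cd.load_specs(
            [
                {"name": "a", "scale": "binary", "levels": ["0", "1"]},
                {"name": "b", "scale": "binary", "levels": ["0", "1"]},
                {"name": "c", "scale": "ordinal", "levels": ["0", "1", "2"]},
                {"name": "y", "scale": "binary", "levels": ["0", "1"], "outcome": True},
            ]
        )
        ds = cd.Dataset(np.column_stack([a, b, c, y]).astype(float), specs)
        g = nx.DiGraph([("a", "b"), ("b", "y"), ("c", "y")])
        g.add_nodes_from(ds.names)
        assert cd.bic_score(g, ds) == pytest.approx(brute_force_bic(g, ds), abs=1e-9)

    def test_cyclic_graph_rejected(self):
        ds = _binary_dataset({"a": np.zeros(4), "b": np.ones(4)}, "b")
        with pytest.raises(ValueError, match="cycle"):
            cd.bic_score(nx.DiGraph([("a", "b"), ("b", "a")]), ds)

    def test_continuous_column_rejected(self):
        specs = cd.load_specs(
            [
                {"name": "x", "scale": "continuous"},
                {"name": "y", "scale": "binary", "levels": ["0", "1"], "outcome": True},
            ]
        )
        ds = cd.Dataset(np.column_stack([np.random.default_rng(0).normal(size=6), np.r_[0, 1, 0, 1, 0, 1]]), specs)
        g = nx.DiGraph()
        g.add_nodes_from(["x", "y"])
        with pytest.raises(ValueError, match="continuous"):
            cd.bic_score(g, ds)


def _singleton(n):
    g = nx.DiGraph()
    g.add_node(n)
    return g


class TestApplyThreshold:
    def test_zero_threshold_is_identity(self):
        w = cd.WeightMatrix(np.array([[0, 0.05], [0.2, 0]]), ["a", "b"])
        np.testing.assert_array_equal(cd.apply_threshold(w, 0.0).W, w.W)

    def test_above_max_zeroes_everything(self):
        w = cd.WeightMatrix(np.array([[0, 0.05], [0.2, 0]]), ["a", "b"])
        assert (cd.apply_threshold(w, 99.0).W == 0).all()

    def test_elementwise_magnitude_rule(self):
        w = cd.WeightMatrix(
            np.array([[0, 0.05, 0.15], [0, 0, -0.2], [0, 0, 0]]), ["a", "b", "c"]
        )
        out = cd.apply_threshold(w, 0.1)
        np.testing.assert_allclose(out.W, [[0, 0, 0.15], [0, 0, -0.2], [0, 0, 0]])

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        W = np.triu(rng.normal(size=(5, 5)), 1)
        w = cd.WeightMatrix(W, [f"n{i}" for i in range(5)])
        for t1, t2 in [(0.0, 0.3), (0.1, 0.5), (0.2, 0.9)]:
            s1 = set(zip(*np.nonzero(cd.apply_threshold(w, t2).W)))
            s2 = set(zip(*np.nonzero(cd.apply_threshold(w, t1).W)))
            assert s1 <= s2


class TestThresholdCurve:
    def test_curve_on_planted_sem(self, stemilike_dataset):
        ds, _ = stemilike_dataset
        discrete, _ = cd.discretize_dataset(ds)
        w = cd.notears_fit(discrete.values, nodes=discrete.names)
        grid = np.round(np.linspace(0.0, 0.45, 10), 3)
        curve = cd.build_threshold_curve(w, discrete, grid)
        assert (np.diff(curve.edge_counts) <= 0).all()
        assert curve.thresholds.size == 10
        if curve.edge_counts[-1] == 0:
            empty = nx.DiGraph()
            empty.add_nodes_from(discrete.names)
            assert curve.scores[-1] == pytest.approx(cd.bic_score(empty, discrete))

    def test_threshold_above_max_scores_empty_graph(self):
        rng = np.random.default_rng(1)
        cols = {"a": rng.integers(0, 2, 60), "y": rng.integers(0, 2, 60)}
        ds = _binary_dataset(cols, "y")
        w = cd.WeightMatrix(np.array([[0, 0.4], [0, 0]]), ["a", "y"])
        curve = cd.build_threshold_curve(w, ds, [0.0, 0.2, 0.9])
        empty = nx.DiGraph()
        empty.add_nodes_from(["a", "y"])
        assert curve.edge_counts[-1] == 0
        assert curve.scores[-1] == pytest.approx(cd.bic_score(empty, ds))
        # t=0 scores the full support
        assert curve.edge_counts[0] == 1

    def test_cycle_repair_drops_weakest_edge(self):
        rng = np.random.default_rng(2)
        cols = {"a": rng.integers(0, 2, 80), "y": rng.integers(0, 2, 80)}
        ds = _binary_dataset(cols, "y")
        W = np.array([[0.0, 0.8], [0.3, 0.0]])  # 2-cycle; 0.3 is weakest
        w = cd.WeightMatrix(W, ["a", "y"])
        curve = cd.build_threshold_curve(w, ds, [0.0, 0.5])
        assert curve.edge_counts[0] == 1  # repaired support keeps a->y only


class TestSelectThreshold:
    def test_exactly_linear_curve_returns_smallest(self):
        curve = ThresholdCurve(
            np.linspace(0, 0.5, 6), np.arange(6)[::-1], np.linspace(-100, -50, 6), []
        )
        assert cd.select_threshold(curve) == 0.0

    def test_piecewise_linear_knee_found(self):
        # steep rise until t=0.1, then flat: knee at 0.1
        t = np.round(np.arange(0.0, 0.31, 0.05), 2)
        scores = np.where(t <= 0.1, -200 + 1500 * t, -50 - 10 * (t - 0.1))
        counts = np.arange(len(t))[::-1]
        curve = ThresholdCurve(t, counts, scores, [])
        assert cd.select_threshold(curve) == pytest.approx(0.1)

    def test_requires_three_points(self):
        curve = ThresholdCurve(np.array([0.0, 0.1]), np.array([2, 1]), np.array([-5.0, -4.0]), [])
        with pytest.raises(ValueError, match="3"):
            cd.select_threshold(curve)

    def test_reference_threshold_shipped(self):
        from cohortdag.selection import REFERENCE_THRESHOLD

        assert REFERENCE_THRESHOLD == 0.1
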