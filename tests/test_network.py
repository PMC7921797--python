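"""PCIT against a brute-force trio oracle; centrality closed forms."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import rxpanel as rx
from rxpanel.network import (
    centralities,
    centrality_correlation_table,
    pcit,
    pearson_matrix,
    tissue_of_max_expression,
)


def brute_force_pcit(r: np.ndarray) -> np.ndarray:
    """Trio-enumeration PCIT: explicit loops, no vectorization."""
    n = r.shape[0]

    def partial(x, y, z):
        num = r[x, y] - r[x, z] * r[y, z]
        den = np.sqrt((1 - r[x, z] ** 2) * (1 - r[y, z] ** 2))
        if den < 1e-12:
            return np.sign(num) * 1.0
        return num / den

    dominated = np.zeros((n, n), dtype=bool)
    for x, y, z in itertools.permutations(range(n), 3):
        if x > y:
            continue
        total = 0.0
        for (a, b, c) in ((x, y, z), (x, z, y), (y, z, x)):
            if r[a, b] != 0:
                total += partial(a, b, c) / r[a, b]
        tol = total / 3.0
        if abs(r[x, y]) < abs(tol * r[x, z]) and abs(r[x, y]) < abs(tol * r[y, z]):
            dominated[x, y] = dominated[y, x] = True
    sig = ~dominated & (r != 0)
    np.fill_diagonal(sig, False)
    return sig


def random_corr(n: int, rng: np.random.Generator) -> pd.DataFrame:
    x = rng.normal(0, 1, (n, n + 5))
    r = np.corrcoef(x)
    genes = [f"g{i}" for i in range(n)]
    return pd.DataFrame(r, index=genes, columns=genes)


class TestPearson:
    def test_hand_formula_five_points(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 7.0])
        b = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
        expr = pd.DataFrame([a, b, -a], index=["x", "y", "negx"])
        r = pearson_matrix(expr)
        expected = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert r.loc["x", "y"] == pytest.approx(expected, abs=1e-12)
        assert r.loc["x", "x"] == 1.0
        assert r.loc["x", "negx"] == pytest.approx(-1.0, abs=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pearson_matrix(pd.DataFrame(np.ones((3, 2))))

    def test_zero_variance_gene_dropped_with_warning(self):
        expr = pd.DataFrame(
            [[1, 2, 3, 4], [2, 2, 2, 2], [4, 3, 2, 1]], index=["a", "b", "c"]
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            r = pearson_matrix(expr)
        assert list(r.index) == ["a", "c"]


class TestPCIT:
    def test_closed_form_trio_partial(self):
        r = pd.DataFrame(
            [[1, 0.9, 0.6], [0.9, 1, 0.5], [0.6, 0.5, 1]],
            index=list("ABC"), columns=list("ABC"),
        )
        part = (0.9 - 0.6 * 0.5) / np.sqrt((1 - 0.36) * (1 - 0.25))
        assert part == pytest.approx(0.6 / np.sqrt(0.48), abs=1e-12)
        flags = pcit(r)
        oracle = brute_force_pcit(r.to_numpy())
        assert (flags.to_numpy() == oracle).all()

    def test_identity_matrix_no_edges(self):
        ident = pd.DataFrame(
            np.eye(6), index=list("abcdef"), columns=list("abcdef")
        )
        assert pcit(ident).to_numpy().sum() == 0

    def test_matches_oracle_on_random_matrices(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            n = int(rng.integers(4, 11))
            corr = random_corr(n, rng)
            flags = pcit(corr).to_numpy()
            assert (flags == brute_force_pcit(corr.to_numpy())).all()

    def test_invariance_under_reordering_and_sign_flip(self):
        rng = np.random.default_rng(5)
        corr = random_corr(8, rng)
        flags = pcit(corr)
        perm = rng.permutation(8)
        genes = corr.index[perm]
        reordered = pcit(corr.loc[genes, genes])
        pd.testing.assert_frame_equal(
            reordered.loc[corr.index, corr.columns], flags
        )
        flip = corr.copy()
        flip.iloc[0, 1:] *= -1
        flip.iloc[1:, 0] *= -1
        pd.testing.assert_frame_equal(pcit(flip), flags)


class TestBuildNetwork:
    def test_empty_and_size_bounds(self, small_norm):
        net = rx.build_network(small_norm.filtered_log_expr, [])
        assert net.graph.number_of_nodes() == 0
        genes = small_norm.retained_genes[:10]
        net = rx.build_network(small_norm.filtered_log_expr, genes)
        assert net.n_edges <= 10 * 9 / 2

    def test_module_genes_form_connected_cluster(self, small_dataset, small_norm):
        mods = {m: [] for m in set(small_dataset.truth_modules.values())}
        for g, m in small_dataset.truth_modules.items():
            mods[m].append(g)
        genes = sorted(mods[0]) + sorted(mods[1])
        net = rx.build_network(small_norm.filtered_log_expr, genes)
        sub0 = net.graph.subgraph(mods[0])
        assert nx.is_connected(sub0)
        within = sub0.number_of_edges() / (len(mods[0]) * (len(mods[0]) - 1) / 2)
        n_cross_pairs = len(mods[0]) * len(mods[1])
        cross = (
            sum(1 for a, b in net.graph.edges()
                if (a in set(mods[0])) != (b in set(mods[0])))
            / n_cross_pairs
        )
        assert cross < within / 2  # cross-module edges are rare

    def test_exports(self, small_norm, tmp_path):
        genes = small_norm.retained_genes[:8]
        net = rx.build_network(small_norm.filtered_log_expr, genes)
        net.write_sif(tmp_path / "net.sif")
        net.write_tsv(tmp_path / "net.tsv")
        back = pd.read_csv(tmp_path / "net.tsv", sep="\t")
        assert len(back) == net.n_edges
        assert list(back.columns) == ["gene_a", "gene_b", "r", "significant"]


class TestCentralities:
    def _table(self, g):
        return centralities(rx.GeneNetwork(graph=g))

    def test_triangle(self):
        t = self._table(nx.complete_graph(3))
        assert (t["clustering"] == 1.0).all()
        assert (t["betweenness"] == 0.0).all()
        assert (t["degree"] == 2).all()
        assert (t["closeness"] == 1.0).all()

    def test_star_with_three_leaves(self):
        t = self._table(nx.star_graph(3))
        assert t.loc[0, "betweenness"] == 3.0  # C(3,2) leaf pairs
        assert t.loc[0, "degree"] == 3
        assert (t.loc[1:, "betweenness"] == 0.0).all()
        assert t.loc[1, "closeness"] == pytest.approx(3 / 5)

    def test_path_three_nodes(self):
        g = nx.path_graph(3)  # A-B-C
        t = self._table(g)
        assert t.loc[1, "closeness"] == pytest.approx(1.0)
        assert t.loc[0, "closeness"] == pytest.approx(2 / 3)
        assert t.loc[1, "betweenness"] == 1.0
        assert t.loc[0, "radiality"] == pytest.approx((2 + 1 - 1.5) / 2)

    def test_complete_graph_closed_forms(self):
        t = self._table(nx.complete_graph(5))
        assert (t["betweenness"] == 0.0).all()
        assert (t["clustering"] == 1.0).all()
        assert (t["degree"] == 4).all()
        assert (t["neighborhood"] == 4.0).all()
        assert (t["radiality"] == 1.0).all()

    def test_singleton_conventions(self):
        g = nx.Graph()
        g.add_nodes_from(["lone"])
        g.add_edge("a", "b")
        t = self._table(g)
        assert t.loc["lone", "closeness"] == 0.0
        assert t.loc["lone", "radiality"] == 0.0
        assert t.loc["lone", "neighborhood"] == 0.0


class TestGainCorrelation:
    def test_gain_equal_degree_gives_unit_r(self):
        g = nx.star_graph(4)
        t = centralities(rx.GeneNetwork(graph=g))
        gain = t["degree"].astype(float)
        r = rx.gain_centrality_correlation(gain, t)
        assert r["degree"] == pytest.approx(1.0)

    def test_formula_oracle_ten_nodes(self, rng):
        g = nx.gnm_random_graph(10, 18, seed=1)
        t = centralities(rx.GeneNetwork(graph=g))
        gain = pd.Series(rng.random(10), index=t.index)
        r = rx.gain_centrality_correlation(gain, t)
        for col in t.columns:
            c = t[col].to_numpy()
            if np.std(c) == 0:
                assert np.isnan(r[col])
            else:
                expected = np.corrcoef(gain.to_numpy(), c)[0, 1]
                assert r[col] == pytest.approx(expected, abs=1e-12)

    def test_average_row(self):
        per = {
            "liver": pd.Series({"degree": 0.2, "betweenness": 0.4}),
            "muscle": pd.Series({"degree": 0.4, "betweenness": 0.0}),
        }
        table = centrality_correlation_table(per)
        assert table.loc["AVERAGE", "degree"] == pytest.approx(0.3)


class TestCrossTissue:
    @pytest.fixture(scope="class")
    def tissue_exprs(self):
        cfg = rx.SimulationConfig(
            n_genes=150, n_de=10, n_tissues=3, n_modules=2,
            module_size=10, module_rho=0.8, seed=17,
        )
        ds = rx.simulate_dataset(cfg)
        le = {t: rx.normalize(cm).filtered_log_expr for t, cm in ds.counts.items()}
        genes = sorted(ds.truth_modules) + sorted(ds.truth_de["adrenal"])[:6]
        return ds, le, genes

    def test_handshake_identity(self, tissue_exprs):
        ds, le, genes = tissue_exprs
        nl, nh, dc = rx.cross_tissue_networks(le, genes, ds.labels)
        assert dc.per_gene["delta"].sum() == 2 * (nh.n_edges - nl.n_edges)

    def test_identical_groups_give_identical_networks(self, tissue_exprs):
        ds, le, genes = tissue_exprs
        # mirror HFE columns onto LFE columns -> groups identical
        mirrored = {}
        h = ds.labels.index[ds.labels == "HFE"].tolist()
        l = ds.labels.index[ds.labels == "LFE"].tolist()
        for t, expr in le.items():
            e = expr.copy()
            e[l] = expr[h].to_numpy()
            mirrored[t] = e
        nl, nh, dc = rx.cross_tissue_networks(mirrored, genes, ds.labels)
        assert set(nl.graph.edges()) == set(nh.graph.edges())
        assert (dc.per_gene["delta"] == 0).all()

    def test_tissue_coloring_follows_max_expression(self, tissue_exprs):
        ds, le, genes = tissue_exprs
        boosted = {t: e.copy() for t, e in le.items()}
        tissues = list(boosted)
        boosted[tissues[2]].loc[genes[0]] += 10.0
        color = tissue_of_max_expression(boosted, genes)
        assert color[genes[0]] == tissues[2]

    def test_missing_gene_excluded_with_warning(self, tissue_exprs):
        ds, le, genes = tissue_exprs
        le2 = {t: e.copy() for t, e in le.items()}
        first = list(le2)[0]
        le2[first] = le2[first].drop(index=genes[0])
        with pytest.warns(UserWarning, match="excluded"):
            nl, nh, dc = rx.cross_tissue_networks(le2, genes, ds.labels)
        assert genes[0] not in dc.per_gene["gene_id"].tolist()
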