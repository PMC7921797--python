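"""PCIT co-expression networks, centralities, differential connectivity.

PCIT (partial correlation and information theory) keeps a gene-pair
correlation only if no third gene explains it: for every trio
(x, y, z) the three first-order partial correlations

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

are formed, the trio tolerance is one third of the sum of the
partial-to-direct ratios (terms with a zero direct correlation are
skipped), and the pair (x, y) is *dominated* in the trio if |r_xy| is
below the tolerance-scaled magnitude of both other correlations. A
pair is significant iff it is dominated in no trio.

Node centralities follow the conventions of the Cytoscape Network
Analyzer: betweenness as raw shortest-path pair fractions, closeness
as the reciprocal of the mean shortest-path distance within the
component, radiality against the component diameter, neighborhood
connectivity as mean neighbor degree, and the topological coefficient
over nodes sharing at least one neighbor. Edges are treated as
unweighted for topology; the signed correlation survives only as an
edge attribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

CENTRALITY_COLUMNS = (
    "betweenness",
    "degree",
    "closeness",
    "clustering",
    "neighborhood",
    "radiality",
    "topological",
)


def pearson_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene-gene Pearson correlations from a genes x samples frame.

    Needs at least 3 samples; zero-variance genes are dropped with a
    warning (they have no defined correlation).
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlations")
    sd = expr.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = expr.index[~keep].tolist()
        warnings.warn(f"dropping zero-variance genes: {dropped}")
        expr = expr.loc[keep]
    r = np.corrcoef(expr.to_numpy(dtype=float))
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=expr.index, columns=expr.index)


def _partial_tensor(r: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """P[z, x, y] = first-order partial correlation of (x, y) given z.

    Degenerate denominators (|r| = 1 off-diagonal) saturate the partial
    at sign(numerator) * 1.
    """
    n = r.shape[0]
    p = np.empty((n, n, n))
    for z in range(n):
        rz = r[:, z]
        num = r - np.outer(rz, rz)
        den = np.sqrt(np.outer(1.0 - rz**2, 1.0 - rz**2))
        with np.errstate(divide="ignore", invalid="ignore"):
            pz = num / den
        bad = den < eps
        pz[bad] = np.sign(num[bad]) * 1.0
        p[z] = pz
    return p


def pcit(corr: pd.DataFrame) -> pd.DataFrame:
    """Boolean significance flags for every unordered gene pair.

    Pairs with exactly zero correlation carry no association and are
    never significant (the domination rule alone cannot discard them).
    Vectorized over the controlled gene z; exact flag-set equality with
    a brute-force trio enumeration is part of the test suite.
    """
    genes = corr.index
    r = corr.to_numpy(dtype=float)
    n = r.shape[0]
    if n < 3:
        raise ValueError("PCIT needs at least 3 genes")
    p = _partial_tensor(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_r = np.where(r != 0, 1.0 / r, 0.0)
    dominated = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)
    for z in range(n):
        pz = p[z]  # P[z, x, y]
        pslice = p[:, :, z]  # pslice[a, b] = P[a, b, z]
        ratio1 = pz * inv_r  # r_xy.z / r_xy
        # r_xz.y / r_xz : partial of (x, z) given y, direct r[x, z]
        ratio2 = pslice.T * inv_r[:, z][:, None]
        # r_yz.x / r_yz : partial of (y, z) given x, direct r[y, z]
        ratio3 = pslice * inv_r[:, z][None, :]
        tol = (ratio1 + ratio2 + ratio3) / 3.0
        absr = np.abs(r)
        cond = (absr < np.abs(tol * r[:, z][:, None])) & (
            absr < np.abs(tol * r[:, z][None, :])
        )
        cond[z, :] = False
        cond[:, z] = False
        cond[idx, idx] = False
        dominated |= cond
    significant = ~dominated & (r != 0)
    significant[idx, idx] = False
    return pd.DataFrame(significant, index=genes, columns=genes)


@dataclass
class GeneNetwork:
    """Undirected co-expression graph over a gene panel.

    Nodes carry ``gain`` and ``tissue`` attributes when known; edges
    carry the signed Pearson ``r`` of the PCIT-significant pair.
    Isolated genes are retained as nodes.
    """

    graph: nx.Graph
    label: str = ""

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> pd.Series:
        return pd.Series(dict(self.graph.degree()), name="degree").astype(int)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "r": d.get("r", np.nan), "significant": True}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "significant"])

    def write_sif(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            seen = set()
            for a, b in self.graph.edges():
                fh.write(f"{a}\tco\t{b}\n")
                seen.update((a, b))
            for node in self.graph.nodes():
                if node not in seen:
                    fh.write(f"{node}\n")

    def write_tsv(self, path: str | Path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False)


def build_network(
    expr: pd.DataFrame,
    genes: list[str],
    gain: pd.Series | None = None,
    label: str = "",
) -> GeneNetwork:
    """PCIT network over ``genes`` from their expression profiles.

    Zero-variance genes cannot enter the correlation matrix and stay
    isolated; with fewer than 3 correlatable genes the network has no
    edges.
    """
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing}")
    g = nx.Graph()
    g.add_nodes_from(genes)
    if gain is not None:
        nx.set_node_attributes(
            g, {gene: float(gain.get(gene, 0.0)) for gene in genes}, "gain"
        )
    sub = expr.loc[genes]
    sd = sub.std(axis=1, ddof=0)
    usable = sub.index[sd > 0].tolist()
    if len(usable) >= 3:
        corr = pearson_matrix(sub.loc[usable])
        flags = pcit(corr)
        arr = flags.to_numpy()
        names = flags.index.tolist()
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if arr[i, j]:
                    g.add_edge(names[i], names[j], r=float(corr.iat[i, j]))
    return GeneNetwork(graph=g, label=label)


def centralities(net: GeneNetwork) -> pd.DataFrame:
    """Seven per-node centralities (Network Analyzer conventions)."""
    g = net.graph
    nodes = list(g.nodes())
    out = pd.DataFrame(index=nodes, columns=list(CENTRALITY_COLUMNS), dtype=float)
    out["degree"] = [g.degree(v) for v in nodes]
    out["betweenness"] = pd.Series(nx.betweenness_centrality(g, normalized=False))
    out["clustering"] = pd.Series(nx.clustering(g))

    closeness = {}
    radiality = {}
    for comp in nx.connected_components(g):
        comp = list(comp)
        if len(comp) == 1:
            closeness[comp[0]] = 0.0
            radiality[comp[0]] = 0.0
            continue
        sub = g.subgraph(comp)
        dist = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(d.values()) for d in dist.values())
        for v in comp:
            dv = [dist[v][w] for w in comp if w != v]
            mean_d = float(np.mean(dv))
            closeness[v] = 1.0 / mean_d
            radiality[v] = (diam + 1.0 - mean_d) / diam if diam > 0 else 0.0
    out["closeness"] = pd.Series(closeness)
    out["radiality"] = pd.Series(radiality)

    neigh = {}
    for v in nodes:
        nb = list(g.neighbors(v))
        neigh[v] = float(np.mean([g.degree(w) for w in nb])) if nb else 0.0
    out["neighborhood"] = pd.Series(neigh)

    topo = {}
    for v in nodes:
        nv = set(g.neighbors(v))
        if len(nv) < 2:
            topo[v] = 0.0
            continue
        shared_scores = []
        for w in g.nodes():
            if w == v:
                continue
            nw = set(g.neighbors(w))
            shared = len(nv & nw)
            if shared == 0:
                continue
            shared_scores.append((shared + (1 if w in nv else 0)) / len(nv))
        topo[v] = float(np.mean(shared_scores)) if shared_scores else 0.0
    out["topological"] = pd.Series(topo)
    return out


def gain_centrality_correlation(
    gain: pd.Series, centrality_table: pd.DataFrame
) -> pd.Series:
    """Pearson r between Gain and each centrality column.

    Constant columns have no defined correlation and are reported as
    NaN.
    """
    common = centrality_table.index.intersection(gain.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared nodes")
    gvals = gain[common].to_numpy(dtype=float)
    out = {}
    for col in centrality_table.columns:
        c = centrality_table.loc[common, col].to_numpy(dtype=float)
        if np.std(c) == 0 or np.std(gvals) == 0:
            out[col] = np.nan
        else:
            out[col] = float(np.corrcoef(gvals, c)[0, 1])
    return pd.Series(out, name="pearson_r")


def centrality_correlation_table(per_tissue: dict[str, pd.Series]) -> pd.DataFrame:
    """Stack per-tissue Gain-centrality correlations with an AVERAGE row."""
    table = pd.DataFrame(per_tissue).T
    table.loc["AVERAGE"] = table.mean(axis=0)
    return table


@dataclass
class DifferentialConnectivity:
    """Per-gene and per-tissue connectivity changes between two networks."""

    per_gene: pd.DataFrame  # gene, degree_lfe, degree_hfe, delta
    per_tissue: pd.DataFrame  # tissue, connections_lfe, connections_hfe, pct_change

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_gene.to_csv(outdir / "differential_connectivity.csv", index=False)
        self.per_tissue.to_csv(outdir / "tissue_connectivity.csv", index=False)


def tissue_of_max_expression(
    log_expr_by_tissue: dict[str, pd.DataFrame], genes: list[str]
) -> pd.Series:
    """Assign each gene the tissue where its mean expression is highest."""
    means = pd.DataFrame(
        {
            tissue: expr.reindex(genes).mean(axis=1)
            for tissue, expr in log_expr_by_tissue.items()
        }
    )
    return means.idxmax(axis=1).rename("tissue")


def cross_tissue_networks(
    log_expr_by_tissue: dict[str, pd.DataFrame],
    genes: list[str],
    labels: pd.Series,
    positive_class: str = "HFE",
) -> tuple[GeneNetwork, GeneNetwork, DifferentialConnectivity]:
    """Group-specific (HFE vs LFE) networks over cross-tissue profiles.

    Genes must be quantified in every tissue (others are excluded with
    a warning). For each group, every animal contributes one
    observation column per tissue — the tissues are stacked as extra
    observations so that a handful of animals can still support the
    correlation estimate of a large panel. Each gene is colored by its
    tissue of maximum average expression; per-tissue connection counts
    sum the degrees of that tissue's genes, and the per-gene delta is
    the HFE minus LFE degree.
    """
    usable = [
        g
        for g in genes
        if all(g in expr.index for expr in log_expr_by_tissue.values())
    ]
    dropped = sorted(set(genes) - set(usable))
    if dropped:
        warnings.warn(f"genes not expressed in all tissues excluded: {dropped}")
    if not usable:
        raise ValueError("no gene is expressed in all tissues")

    tissue_color = tissue_of_max_expression(log_expr_by_tissue, usable)
    groups = {}
    for cls in labels.unique():
        animals = labels.index[labels == cls].tolist()
        if len(animals) < 3:
            raise ValueError(f"group {cls!r} has fewer than 3 animals")
        stacked = pd.concat(
            [
                expr.loc[usable, [a for a in animals if a in expr.columns]].rename(
                    columns=lambda c, t=tissue: f"{c}@{t}"
                )
                for tissue, expr in log_expr_by_tissue.items()
            ],
            axis=1,
        )
        net = build_network(stacked, usable, label=str(cls))
        nx.set_node_attributes(net.graph, tissue_color.to_dict(), "tissue")
        groups[cls] = net

    neg_class = [c for c in groups if c != positive_class][0]
    net_h, net_l = groups[positive_class], groups[neg_class]
    deg_h = net_h.degrees().reindex(usable).fillna(0).astype(int)
    deg_l = net_l.degrees().reindex(usable).fillna(0).astype(int)
    per_gene = pd.DataFrame(
        {
            "gene_id": usable,
            "tissue": tissue_color[usable].to_numpy(),
            "degree_lfe": deg_l.to_numpy(),
            "degree_hfe": deg_h.to_numpy(),
            "delta": (deg_h - deg_l).to_numpy(),
        }
    )
    rows = []
    for tissue in log_expr_by_tissue:
        sel = per_gene["tissue"] == tissue
        c_l = int(per_gene.loc[sel, "degree_lfe"].sum())
        c_h = int(per_gene.loc[sel, "degree_hfe"].sum())
        pct = 100.0 * (c_h - c_l) / c_l if c_l > 0 else np.nan
        rows.append(
            {
                "tissue": tissue,
                "connections_lfe": c_l,
                "connections_hfe": c_h,
                "pct_change": pct,
            }
        )
    return net_l, net_h, DifferentialConnectivity(
        per_gene=per_gene, per_tissue=pd.DataFrame(rows)
    )
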