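"""Thresholded correlation networks and the multilayer immune-lncRNA screen.

Two edge families are built by all-pairs Pearson correlation across
samples: lncRNA-pcRNA co-expression (default |r| > 0.9 and BH-adjusted
p < 0.01) and lncRNA-immunocyte score correlation (default |r| > 0.75 and
raw p < 0.001). LncRNAs with at least one retained cell edge are the
immune-lncRNA candidates; each candidate's correlated protein-coding set
is functionally annotated by over-representation, yielding a three-layer
lncRNA -> immunocyte -> term network exportable as GraphML, an edge list,
or a Sankey-style long table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .data import ImmLncError, SchemaError, SignatureSet
from .enrichment import ora

EDGE_COLUMNS = ["source", "target", "r", "p_value", "p_adjusted", "edge_type"]


def pearson_with_p(x: pd.DataFrame, y: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All row-pairs Pearson r between two feature x sample frames.

    Returns (r, p) DataFrames of shape (rows of x) x (rows of y); p is the
    two-sided t-test p-value on n - 2 degrees of freedom.
    """
    if list(x.columns) != list(y.columns):
        raise SchemaError("sample columns differ between the two matrices")
    n = x.shape[1]
    if n < 3:
        raise ImmLncError("need >= 3 shared samples")
    xa = x.to_numpy(dtype=float)
    ya = y.to_numpy(dtype=float)
    xa = xa - xa.mean(axis=1, keepdims=True)
    ya = ya - ya.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xa, axis=1)
    yn = np.linalg.norm(ya, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xa @ ya.T) / np.outer(xn, yn)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return (
        pd.DataFrame(r, index=x.index, columns=y.index),
        pd.DataFrame(p, index=x.index, columns=y.index),
    )


def _edge_frame(
    r: pd.DataFrame,
    p: pd.DataFrame,
    padj: np.ndarray,
    keep: np.ndarray,
    edge_type: str,
) -> pd.DataFrame:
    src_idx, tgt_idx = np.nonzero(keep)
    rows = {
        "source": r.index.to_numpy()[src_idx],
        "target": r.columns.to_numpy()[tgt_idx],
        "r": r.to_numpy()[src_idx, tgt_idx],
        "p_value": p.to_numpy()[src_idx, tgt_idx],
        "p_adjusted": padj.reshape(r.shape)[src_idx, tgt_idx],
        "edge_type": edge_type,
    }
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def lnc_pc_edges(
    lnc_expr: pd.DataFrame,
    pc_expr: pd.DataFrame,
    r_min: float = 0.9,
    padj_max: float = 0.01,
    positive_only: bool = False,
) -> pd.DataFrame:
    """lncRNA-pcRNA co-expression edges at |r| > r_min, BH p_adj < padj_max."""
    r, p = pearson_with_p(lnc_expr, pc_expr)
    padj = multipletests(p.to_numpy().ravel(), method="fdr_bh")[1]
    mag = r.to_numpy() if positive_only else np.abs(r.to_numpy())
    keep = (mag > r_min) & (padj.reshape(r.shape) < padj_max)
    return _edge_frame(r, p, padj, keep, "lnc_pc")


def lnc_cell_edges(
    lnc_expr: pd.DataFrame,
    normalized_scores: pd.DataFrame,
    r_min: float = 0.75,
    p_max: float = 0.001,
    positive_only: bool = False,
) -> pd.DataFrame:
    """lncRNA-immunocyte edges at |r| > r_min and raw p < p_max.

    ``normalized_scores`` is the infiltration score matrix (cell types x
    samples). Retained edges define the immune-lncRNA candidate set.
    """
    r, p = pearson_with_p(lnc_expr, normalized_scores)
    padj = multipletests(p.to_numpy().ravel(), method="fdr_bh")[1]
    mag = r.to_numpy() if positive_only else np.abs(r.to_numpy())
    keep = (mag > r_min) & (p.to_numpy() < p_max)
    return _edge_frame(r, p, padj, keep, "lnc_cell")


def hub_rank(edges: pd.DataFrame) -> pd.DataFrame:
    """Degree and tercile category (low / mid / high) per lncRNA.

    Categories are terciles of the positive-degree distribution; ties on
    a tercile boundary resolve toward the higher category.
    """
    if edges.empty:
        raise ImmLncError("empty edge list")
    degree = edges.groupby("source").size().astype(int)
    q1, q2 = np.quantile(degree.to_numpy(), [1 / 3, 2 / 3])
    category = pd.Series(
        np.where(degree >= q2, "high", np.where(degree >= q1, "mid", "low")),
        index=degree.index,
    )
    out = pd.DataFrame({"lncRNA": degree.index, "degree": degree.to_numpy(),
                        "category": category.to_numpy()})
    return out.sort_values(["degree", "lncRNA"], ascending=[False, True]).reset_index(drop=True)


@dataclass
class MultilayerNetwork:
    """Typed three-layer network: lncRNA -> immunocyte and lncRNA -> term."""

    nodes: pd.DataFrame  # columns: id, node_type
    cell_edges: pd.DataFrame
    pc_edges: pd.DataFrame
    go_edges: pd.DataFrame  # columns: lncRNA, term_id, p_adjusted, gene_ratio
    unattributed: list[str] = field(default_factory=list)

    @property
    def imm_lncrnas(self) -> list[str]:
        return sorted(self.cell_edges["source"].unique()) if not self.cell_edges.empty else []


def build_multilayer(
    cell_edges: pd.DataFrame,
    pc_edges: pd.DataFrame,
    genesets: SignatureSet,
    universe: Iterable[str],
    ora_padj_max: float = 0.05,
    min_term: int = 3,
    max_term: int = 500,
) -> MultilayerNetwork:
    """Assemble the lncRNA -> immunocyte -> functional-term network.

    Every lncRNA with at least one cell edge is a candidate; its
    correlated protein-coding partners are tested for term
    over-representation against ``universe``, and terms with adjusted
    p < ``ora_padj_max`` become lncRNA -> term edges. Candidates with no
    correlated pcRNAs are kept as nodes, flagged unattributed.
    """
    universe = list(universe)
    go_rows = []
    unattributed: list[str] = []
    candidates = (
        sorted(cell_edges["source"].unique()) if not cell_edges.empty else []
    )
    for lnc in candidates:
        partners = (
            pc_edges.loc[pc_edges["source"] == lnc, "target"].tolist()
            if not pc_edges.empty
            else []
        )
        partners = [g for g in partners if g in universe]
        if not partners:
            unattributed.append(lnc)
            continue
        res = ora(partners, universe, genesets, min_term=min_term, max_term=max_term)
        hits = res[res["p_adjusted"] < ora_padj_max]
        if hits.empty:
            unattributed.append(lnc)
        for row in hits.itertuples():
            go_rows.append(
                {
                    "lncRNA": lnc,
                    "term_id": row.term_id,
                    "p_adjusted": row.p_adjusted,
                    "gene_ratio": row.gene_ratio,
                }
            )
    go_edges = pd.DataFrame(go_rows, columns=["lncRNA", "term_id", "p_adjusted", "gene_ratio"])

    node_rows = [{"id": l, "node_type": "lncRNA"} for l in candidates]
    if not cell_edges.empty:
        node_rows += [
            {"id": c, "node_type": "immunocyte"}
            for c in sorted(cell_edges["target"].unique())
        ]
    pc_used = (
        pc_edges[pc_edges["source"].isin(candidates)]["target"].unique()
        if not pc_edges.empty
        else []
    )
    node_rows += [{"id": g, "node_type": "pcRNA"} for g in sorted(pc_used)]
    if not go_edges.empty:
        node_rows += [
            {"id": t, "node_type": "go_term"} for t in sorted(go_edges["term_id"].unique())
        ]
    nodes = pd.DataFrame(node_rows, columns=["id", "node_type"]).drop_duplicates("id")

    cell_sub = (
        cell_edges[cell_edges["source"].isin(candidates)].reset_index(drop=True)
        if not cell_edges.empty
        else cell_edges
    )
    pc_sub = (
        pc_edges[pc_edges["source"].isin(candidates)].reset_index(drop=True)
        if not pc_edges.empty
        else pc_edges
    )
    return MultilayerNetwork(
        nodes=nodes.reset_index(drop=True),
        cell_edges=cell_sub,
        pc_edges=pc_sub,
        go_edges=go_edges,
        unattributed=unattributed,
    )


def to_graph(net: MultilayerNetwork) -> nx.Graph:
    g = nx.Graph()
    for row in net.nodes.itertuples():
        g.add_node(row.id, node_type=row.node_type)
    for edges in (net.cell_edges, net.pc_edges):
        if edges is None or edges.empty:
            continue
        for row in edges.itertuples():
            g.add_edge(
                row.source, row.target,
                r=float(row.r), p_value=float(row.p_value),
                p_adjusted=float(row.p_adjusted), edge_type=row.edge_type,
            )
    if net.go_edges is not None and not net.go_edges.empty:
        for row in net.go_edges.itertuples():
            g.add_edge(
                row.lncRNA, row.term_id,
                p_adjusted=float(row.p_adjusted),
                gene_ratio=float(row.gene_ratio), edge_type="lnc_go",
            )
    return g


def sankey_table(net: MultilayerNetwork) -> pd.DataFrame:
    """Long-format lncRNA -> immunocyte -> term rows with link weights.

    One row per (cell edge, attached term) pair per lncRNA; weights are
    |r| for the lncRNA-immunocyte link and the term gene ratio for the
    lncRNA-term link.
    """
    rows = []
    for lnc in net.imm_lncrnas:
        cells = net.cell_edges[net.cell_edges["source"] == lnc]
        terms = net.go_edges[net.go_edges["lncRNA"] == lnc] if not net.go_edges.empty else pd.DataFrame()
        for c in cells.itertuples():
            for t in terms.itertuples():
                rows.append(
                    {
                        "lncRNA": lnc,
                        "immunocyte": c.target,
                        "go_term": t.term_id,
                        "cell_weight": abs(float(c.r)),
                        "term_weight": float(t.gene_ratio),
                    }
                )
    return pd.DataFrame(
        rows, columns=["lncRNA", "immunocyte", "go_term", "cell_weight", "term_weight"]
    )


SUPPORTED_FORMATS = ("graphml", "edgelist", "sankey")


def export_network(net: MultilayerNetwork, fmt: str, path: str | Path) -> Path:
    """Write the network as GraphML, an edge-list TSV, or a Sankey TSV."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(to_graph(net), path)
    elif fmt == "edgelist":
        frames = [f for f in (net.cell_edges, net.pc_edges) if f is not None and not f.empty]
        edges = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=EDGE_COLUMNS)
        edges.to_csv(path, sep="\t", index=False)
    elif fmt == "sankey":
        sankey_table(net).to_csv(path, sep="\t", index=False)
    else:
        raise ImmLncError(
            f"unknown format {fmt!r}; supported: {', '.join(SUPPORTED_FORMATS)}"
        )
    return path
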