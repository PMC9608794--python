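"""Centrality analysis of the ceRNA network and hub-lncRNA calling.

Hub lncRNAs are defined by rank intersection: lncRNA nodes are ranked by
degree and by betweenness (computed on the full bipartite network, mRNA
nodes included), the top ``k`` of each ranking are retained — ties at the
k-th value included — and the hubs are the lncRNAs appearing in both
retained sets.

Betweenness is the undirected, unweighted, unnormalized shortest-path
betweenness: each unordered source-target pair is counted once and
endpoints are excluded from their own paths (Brandes' accumulation, as
implemented in networkx).  Normalization conventions cancel in ranking but
are stated so values are comparable across tools.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .cerna import CeRNANetwork

log = logging.getLogger(__name__)


def degree_centrality(net: CeRNANetwork) -> dict:
    """Number of incident edges per node."""
    g = net.to_graph()
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    return dict(g.degree())


def betweenness_centrality(net: CeRNANetwork) -> dict:
    """Unnormalized shortest-path betweenness per node.

    Disconnected components are handled naturally (no paths cross them).
    """
    g = net.to_graph()
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    return nx.betweenness_centrality(g, normalized=False)


def _min_rank(series: pd.Series) -> pd.Series:
    """Competition rank, 1 = highest value, ties share the smallest rank."""
    return series.rank(method="min", ascending=False).astype(int)


@dataclass(frozen=True)
class CentralityReport:
    """Per-node centralities, lncRNA ranks, and the hub intersection.

    ``table`` has one row per network node with columns ``node``, ``type``,
    ``degree``, ``betweenness``, ``degree_rank``, ``betweenness_rank``
    (ranks among lncRNA nodes only; <NA> for mRNAs) and ``is_hub``.
    ``hubs`` is ordered by (betweenness desc, degree desc, id asc).
    """

    table: pd.DataFrame
    hubs: tuple
    k: int


def select_hubs(net: CeRNANetwork, k: int = 8) -> CentralityReport:
    """Call hub lncRNAs as the top-``k`` rank intersection of both metrics.

    All ties at the k-th value are included in each metric's retained set,
    so no node is excluded by an arbitrary tie-break.  If the network has
    fewer than ``k`` lncRNAs, all of them are retained per metric (with a
    warning).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not net.lnc_nodes:
        raise ValueError("network has no lncRNA nodes")
    deg = degree_centrality(net)
    btw = betweenness_centrality(net)
    nodes = sorted(deg)
    df = pd.DataFrame({
        "node": nodes,
        "type": ["lncRNA" if v in net.lnc_nodes else "mRNA" for v in nodes],
        "degree": [deg[v] for v in nodes],
        "betweenness": [btw[v] for v in nodes],
    })
    lnc = df[df["type"] == "lncRNA"].copy()
    if len(lnc) < k:
        log.warning("only %d lncRNA nodes for k=%d; all retained per metric",
                    len(lnc), k)
    lnc["degree_rank"] = _min_rank(lnc["degree"])
    lnc["betweenness_rank"] = _min_rank(lnc["betweenness"])
    top_deg = set(lnc.loc[lnc["degree_rank"] <= k, "node"])
    top_btw = set(lnc.loc[lnc["betweenness_rank"] <= k, "node"])
    hub_set = top_deg & top_btw
    hubs = sorted(hub_set,
                  key=lambda v: (-btw[v], -deg[v], v))
    df = df.merge(lnc[["node", "degree_rank", "betweenness_rank"]],
                  on="node", how="left")
    df["degree_rank"] = df["degree_rank"].astype("Int64")
    df["betweenness_rank"] = df["betweenness_rank"].astype("Int64")
    df["is_hub"] = df["node"].isin(hub_set)
    df = df.sort_values(["betweenness", "degree", "node"],
                        ascending=[False, False, True],
                        kind="mergesort").reset_index(drop=True)
    return CentralityReport(table=df, hubs=tuple(hubs), k=k)


def write_report(report: CentralityReport, table_path, hubs_path=None) -> None:
    report.table.to_csv(table_path, sep="\t", index=False, float_format="%.10g")
    if hubs_path is not None:
        with open(hubs_path, "w", encoding="utf-8") as fh:
            for h in report.hubs:
                fh.write(h + "\n")
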