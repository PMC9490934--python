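"""The hub-gene funnel.

Starting from per-gene scores in the selected key module:

1. keep genes with GS > 0.5 and MM > 0.9 (strict), split by biotype;
2. restrict the supplied protein-interaction graph to the key mRNAs,
   rank them by unnormalized shortest-path betweenness and keep the top
   20 (ties broken lexicographically);
3. keep the top 10 key lncRNAs by smallest GS p-value;
4. build a lncRNA-mRNA co-expression network over the survivors: all
   mRNA-mRNA and lncRNA-mRNA pairs with |Pearson r| >= 0.9 and p < 0.05
   become edges (lncRNA-lncRNA pairs are not part of this network);
5. hub mRNAs / hub lncRNAs are the key genes with at least one edge.

Every tie-break is fixed so identical inputs yield byte-identical hub
lists. Betweenness is reported as raw pair counts (only ranks matter
for the top-k step); normalization is a display concern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .traits import correlate_with_p

logger = logging.getLogger(__name__)


class SelectionError(ValueError):
    pass


@dataclass
class KeyGeneSet:
    """Genes passing the GS/MM filter in the key module, by biotype.

    Both frames are indexed by symbol and carry GS, MM and GS_p.
    """

    key_lncrna: pd.DataFrame
    key_mrna: pd.DataFrame
    module: str
    gs_cut: float = 0.5
    mm_cut: float = 0.9


@dataclass
class CoexpressionNetwork:
    """Thresholded correlation edges between key genes.

    ``edges`` columns: gene_a, gene_b, r, p, edge_type
    (mRNA-mRNA or lncRNA-mRNA).
    """

    edges: pd.DataFrame
    r_threshold: float
    p_threshold: float


@dataclass
class HubSet:
    hub_mrna: list[str]
    hub_lncrna: list[str]
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)


def filter_key_genes(
    scores: pd.DataFrame,
    annotation: pd.DataFrame,
    module: str,
    gs_cut: float = 0.5,
    mm_cut: float = 0.9,
) -> KeyGeneSet:
    """Key genes of one module: GS > gs_cut and MM > mm_cut (strict)."""
    sub = scores[scores["module"] == module]
    if sub.empty:
        raise SelectionError(f"module {module!r} absent from the score table")
    keep = sub[(sub["GS"] > gs_cut) & (sub["MM"] > mm_cut)]
    ann = annotation.reindex(keep.index)
    out = pd.DataFrame(
        {
            "symbol": ann["symbol"],
            "biotype": ann["biotype"],
            "GS": keep["GS"],
            "MM": keep["MM"],
            "GS_p": keep["GS_p"],
        }
    ).set_index("symbol").sort_index()
    return KeyGeneSet(
        key_lncrna=out[out["biotype"] == "lncRNA"].drop(columns="biotype"),
        key_mrna=out[out["biotype"] == "mRNA"].drop(columns="biotype"),
        module=module,
        gs_cut=gs_cut,
        mm_cut=mm_cut,
    )


def betweenness(edges: pd.DataFrame) -> pd.Series:
    """Unnormalized shortest-path betweenness per node (undirected).

    Multiple shortest paths split credit equally; disconnected
    components contribute no cross-component pairs.
    """
    g = nx.Graph()
    g.add_edges_from(edges[["gene_a", "gene_b"]].itertuples(index=False, name=None))
    if g.number_of_nodes() == 0:
        return pd.Series(dtype=float, name="betweenness")
    bc = nx.betweenness_centrality(g, normalized=False)
    return pd.Series(bc, name="betweenness").sort_index()


def top_k(table: pd.Series, k: int) -> list[str]:
    """The k highest-scoring symbols; ties break lexicographically."""
    if k < 1:
        raise SelectionError("k must be >= 1")
    if len(table) < k:
        logger.warning("only %d candidates for top-%d; returning all", len(table), k)
    order = sorted(table.items(), key=lambda kv: (-kv[1], kv[0]))
    return [sym for sym, _ in order[:k]]


def top_lncrnas_by_p(key: KeyGeneSet, k: int = 10) -> list[str]:
    """The k key lncRNAs with the smallest GS p-value (ties by symbol)."""
    if k < 1:
        raise SelectionError("k must be >= 1")
    if len(key.key_lncrna) < k:
        logger.warning(
            "only %d key lncRNAs for top-%d; returning all", len(key.key_lncrna), k
        )
    order = sorted(key.key_lncrna["GS_p"].items(), key=lambda kv: (kv[1], kv[0]))
    return [sym for sym, _ in order[:k]]


def induced_subgraph(edges: pd.DataFrame, nodes) -> pd.DataFrame:
    """Edges with both endpoints in ``nodes``."""
    nodes = set(nodes)
    mask = edges["gene_a"].isin(nodes) & edges["gene_b"].isin(nodes)
    return edges[mask].reset_index(drop=True)


def coexpression_network(
    expr: pd.DataFrame,
    lncrnas: list[str],
    mrnas: list[str],
    r_threshold: float = 0.9,
    p_threshold: float = 0.05,
) -> CoexpressionNetwork:
    """lncRNA-mRNA and mRNA-mRNA co-expression edges between key genes.

    An edge is kept iff |r| >= r_threshold (inclusive) and p < p_threshold.
    ``expr`` must be indexed by symbol.
    """
    missing = (set(lncrnas) | set(mrnas)) - set(expr.index)
    if missing:
        raise SelectionError(f"gene(s) absent from expression: {sorted(missing)}")
    rows = []

    def test_pair(a: str, b: str, kind: str) -> None:
        r, p = correlate_with_p(expr.loc[a].to_numpy(), expr.loc[b].to_numpy())
        if abs(r) >= r_threshold and p < p_threshold:
            x, y = (a, b) if a < b else (b, a)
            rows.append({"gene_a": x, "gene_b": y, "r": r, "p": p, "edge_type": kind})

    mr = sorted(set(mrnas))
    ln = sorted(set(lncrnas))
    for i, a in enumerate(mr):
        for b in mr[i + 1:]:
            test_pair(a, b, "mRNA-mRNA")
    for a in ln:
        for b in mr:
            test_pair(a, b, "lncRNA-mRNA")
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p", "edge_type"])
    edges = edges.sort_values(["gene_a", "gene_b"], kind="mergesort").reset_index(drop=True)
    return CoexpressionNetwork(edges=edges, r_threshold=r_threshold,
                               p_threshold=p_threshold)


def final_hubs(
    network: CoexpressionNetwork,
    key_mrnas: list[str],
    key_lncrnas: list[str],
    betweenness_table: pd.Series | None = None,
    key: KeyGeneSet | None = None,
) -> HubSet:
    """Hub genes: the top-k key genes with >= 1 co-expression edge.

    Provenance records, per hub, its degree in the network plus (when
    available) betweenness rank and GS/MM.
    """
    if network.edges.empty:
        logger.warning("empty co-expression network: hub sets are empty")
    deg: dict[str, int] = {}
    for _, e in network.edges.iterrows():
        deg[e["gene_a"]] = deg.get(e["gene_a"], 0) + 1
        deg[e["gene_b"]] = deg.get(e["gene_b"], 0) + 1
    hub_mrna = [g for g in key_mrnas if deg.get(g, 0) > 0]
    hub_lncrna = [g for g in key_lncrnas if deg.get(g, 0) > 0]

    bt_rank = {}
    if betweenness_table is not None:
        for rank, sym in enumerate(top_k(betweenness_table, max(1, len(betweenness_table))), 1):
            bt_rank[sym] = rank
    records = []
    for g in hub_mrna + hub_lncrna:
        rec = {
            "symbol": g,
            "biotype": "mRNA" if g in hub_mrna else "lncRNA",
            "degree": deg.get(g, 0),
            "betweenness_rank": bt_rank.get(g, np.nan),
        }
        if key is not None:
            table = key.key_mrna if g in key.key_mrna.index else key.key_lncrna
            if g in table.index:
                rec["GS"] = float(table.loc[g, "GS"])
                rec["MM"] = float(table.loc[g, "MM"])
        records.append(rec)
    prov = pd.DataFrame(records)
    if not prov.empty:
        prov = prov.set_index("symbol")
    return HubSet(hub_mrna=hub_mrna, hub_lncrna=hub_lncrna, provenance=prov)
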