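"""Anchored interaction networks and category enrichment.

Builds the blastema-anchored subnetwork from a scored functional
interaction table (STRING-style gene_a / gene_b / score rows, scores taken
as-is), extracts the top-scoring core by a nearest-rank quantile threshold,
overlays miRNA->gene regulatory edges from target prediction, and tests
gene-set enrichment with a one-sided hypergeometric test.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr

logger = logging.getLogger(__name__)

TOP_FRACTION = 0.02


def anchored_subnetwork(
    interactions: pd.DataFrame,
    anchors: Iterable[str],
    candidates: Iterable[str] | None = None,
    mode: str = "direct",
) -> nx.Graph:
    """Subnetwork of scored interactions around a set of anchor genes.

    Keeps edges whose endpoints both lie in anchors + candidates
    (candidates None = unrestricted) and that touch at least one anchor
    (``direct`` mode). Self-loops and duplicate unordered pairs are
    dropped (first occurrence wins). Anchor nodes are always present, even
    when isolated; other nodes exist only as endpoints of kept edges.
    """
    anchors = set(anchors)
    if not anchors:
        raise ValueError("anchors must be non-empty")
    if mode != "direct":
        raise ValueError(f"unknown mode {mode!r}")
    allowed = None if candidates is None else set(candidates) | anchors
    g = nx.Graph()
    for a in sorted(anchors):
        g.add_node(a, is_anchor=True, node_kind="gene")
    seen: set[frozenset] = set()
    for _, row in interactions.iterrows():
        a, b, score = str(row["gene_a"]), str(row["gene_b"]), float(row["score"])
        if a == b:
            continue
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        if allowed is not None and (a not in allowed or b not in allowed):
            continue
        if a not in anchors and b not in anchors:
            continue
        for node in (a, b):
            if node not in g:
                g.add_node(node, is_anchor=node in anchors, node_kind="gene")
        g.add_edge(a, b, score=score, kind="functional")
    return g


def top_fraction_threshold(
    scores: Sequence[float], fraction: float = TOP_FRACTION
) -> tuple[float, np.ndarray]:
    """Score cutoff retaining roughly the top ``fraction`` of edges.

    The threshold is the nearest-rank (1 - fraction) quantile of the
    scores (the value at rank ceil((1 - f) * n) of the ascending order);
    retained entries score *strictly* greater, so ties at the threshold are
    excluded -- with all-equal scores nothing is retained.
    Returns (threshold, boolean retain mask in input order).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one score")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rank = math.ceil((1 - fraction) * scores.size)  # 1-based nearest rank
    threshold = float(np.sort(scores)[rank - 1])
    return threshold, scores > threshold


def top_core(graph: nx.Graph, fraction: float = TOP_FRACTION) -> nx.Graph:
    """Subgraph of functional edges strictly above the top-fraction cutoff."""
    edges = [
        (a, b, d) for a, b, d in graph.edges(data=True) if d.get("kind") == "functional"
    ]
    if not edges:
        return nx.Graph()
    _, mask = top_fraction_threshold([d["score"] for _, _, d in edges], fraction)
    core = nx.Graph()
    for (a, b, d), keep in zip(edges, mask):
        if keep:
            for node in (a, b):
                core.add_node(node, **graph.nodes[node])
            core.add_edge(a, b, **d)
    return core


def integrate_regulatory_edges(
    graph: nx.Graph,
    pairs: pd.DataFrame,
    mirna_log2fc: Mapping[str, float] | None = None,
) -> nx.Graph:
    """Overlay miRNA->gene regulatory edges onto a functional network.

    ``pairs`` has columns mirna / gene / best_score. miRNA nodes are added
    as node_kind='mirna'; edges get kind='regulatory' with the best duplex
    score. Adding the same pair twice is idempotent. Pairs pointing at
    genes absent from the network are skipped with a warning.
    """
    g = graph.copy()
    for _, row in pairs.iterrows():
        mirna, gene = str(row["mirna"]), str(row["gene"])
        if gene not in g or g.nodes[gene].get("node_kind") != "gene":
            logger.warning("skipping regulatory pair %s -> %s: gene not in network", mirna, gene)
            continue
        if mirna not in g:
            attrs = {"node_kind": "mirna", "is_anchor": False}
            if mirna_log2fc and mirna in mirna_log2fc:
                attrs["log2fc"] = float(mirna_log2fc[mirna])
            g.add_node(mirna, **attrs)
        g.add_edge(mirna, gene, score=float(row.get("best_score", 0.0)), kind="regulatory")
    return g


def set_node_fold_changes(graph: nx.Graph, log2fc: Mapping[str, float]) -> None:
    """Attach anchor-species log2 fold changes as node attributes in place."""
    for node, value in log2fc.items():
        if node in graph:
            graph.nodes[node]["log2fc"] = float(value)


def hypergeom_enrichment(
    query: Iterable[str],
    categories: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric (upper-tail) category enrichment.

    For each category: N = universe size, K = category members within the
    universe, n = query size, k = hits; p = P(X >= k) for
    X ~ Hypergeom(N, K, n). BH-FDR is applied across categories.
    """
    universe = set(universe)
    query = set(query)
    if not query:
        raise ValueError("query set must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    n_univ, n_query = len(universe), len(query)
    rows = []
    for cat in sorted(categories):
        members = set(categories[cat]) & universe
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, n_univ, len(members), n_query))
        rows.append(
            {"category": cat, "k": k, "K": len(members), "n": n_query, "N": n_univ,
             "p_value": min(1.0, p)}
        )
    df = pd.DataFrame(rows, columns=["category", "k", "K", "n", "N", "p_value"])
    df["fdr"] = bh_fdr(df["p_value"]) if not df.empty else []
    return df


def _escape(value: str) -> str:
    return value.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unescape(value: str) -> str:
    out, i = [], 0
    while i < len(value):
        if value[i] == "\\" and i + 1 < len(value):
            out.append({"t": "\t", "n": "\n", "\\": "\\"}.get(value[i + 1], value[i + 1]))
            i += 2
        else:
            out.append(value[i])
            i += 1
    return "".join(out)


def export_graph(graph: nx.Graph, path: str | Path, format: str = "edge-tsv") -> None:
    """Write a network as GraphML or a two-section edge TSV (round-trip safe)."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path)
        return
    if format != "edge-tsv":
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w", newline="") as handle:
        handle.write("#nodes\tid\tnode_kind\tis_anchor\tlog2fc\n")
        for node in sorted(graph.nodes):
            d = graph.nodes[node]
            handle.write(
                "node\t{}\t{}\t{}\t{}\n".format(
                    _escape(str(node)),
                    d.get("node_kind", "gene"),
                    int(bool(d.get("is_anchor", False))),
                    d.get("log2fc", ""),
                )
            )
        handle.write("#edges\ta\tb\tscore\tkind\n")
        for a, b in sorted(graph.edges):
            d = graph.edges[a, b]
            handle.write(
                "edge\t{}\t{}\t{}\t{}\n".format(
                    _escape(str(a)), _escape(str(b)), d.get("score", ""), d.get("kind", "")
                )
            )


def import_graph(path: str | Path, format: str = "edge-tsv") -> nx.Graph:
    """Inverse of :func:`export_graph`."""
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format != "edge-tsv":
        raise ValueError(f"unknown format {format!r}")
    g = nx.Graph()
    with open(path) as handle:
        for line in handle:
            if not line.rstrip("\n") or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "node":
                _, node, kind, is_anchor, lfc = parts
                attrs = {"node_kind": kind, "is_anchor": bool(int(is_anchor))}
                if lfc:
                    attrs["log2fc"] = float(lfc)
                g.add_node(_unescape(node), **attrs)
            elif parts[0] == "edge":
                _, a, b, score, kind = parts
                attrs = {"kind": kind}
                if score:
                    attrs["score"] = float(score)
                g.add_edge(_unescape(a), _unescape(b), **attrs)
    return g
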