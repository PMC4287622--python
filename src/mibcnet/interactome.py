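"""Merged protein–protein interaction network and phenotype-induced subgraph.

Interaction records from several source databases (e.g. IntAct, BioGRID,
Reactome exports reduced to symbol-pair edge lists) are merged into one simple
undirected graph over official gene symbols, keeping per-edge source
provenance. The disease feature set is then mapped onto that network: the
induced subgraph keeps only edges whose two endpoints are both disease
features, and the connectivity filter discards features with no interaction to
another feature — interaction evidence acting as an orthogonal filter on the
statistically derived gene list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: (symbol_a, symbol_b, source_database)
EdgeRecord = tuple[str, str, str]


def load_edges(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[EdgeRecord]:
    """Parse an interaction edge list into (A, B, source) records.

    Expects two interactor columns (default headers ``interactor_a`` /
    ``interactor_b``) and an optional ``source_db`` column. Symbols are
    uppercased and trimmed. The parser does not deduplicate or drop
    self-pairs — merging handles that.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge list not found: {path}")
    colmap = {"interactor_a": "interactor_a", "interactor_b": "interactor_b", "source_db": "source_db"}
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    a_col, b_col = colmap["interactor_a"], colmap["interactor_b"]
    missing = {a_col, b_col} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing interactor columns {sorted(missing)}")
    src_col = colmap["source_db"] if colmap["source_db"] in df.columns else None

    records: list[EdgeRecord] = []
    n_skipped = 0
    for _, row in df.iterrows():
        a, b = row[a_col], row[b_col]
        if pd.isna(a) or pd.isna(b) or not str(a).strip() or not str(b).strip():
            n_skipped += 1
            continue
        source = str(row[src_col]).strip() if src_col and pd.notna(row[src_col]) else "unspecified"
        records.append((str(a).strip().upper(), str(b).strip().upper(), source))
    if n_skipped:
        logger.info("%s: skipped %d incomplete interaction rows", path, n_skipped)
    return records


def merge_networks(edge_lists: Iterable[Sequence[EdgeRecord]]) -> nx.Graph:
    """Union edge lists into a simple undirected graph.

    Self-loops are removed (a self-interaction must not satisfy the
    connectivity filter later); A–B and B–A collapse to one unordered edge;
    per-edge ``sources`` provenance is unioned across inputs.
    """
    g = nx.Graph()
    n_rows = 0
    n_self = 0
    for edges in edge_lists:
        for a, b, source in edges:
            n_rows += 1
            if a == b:
                # node is kept so a self-interaction never satisfies the
                # connectivity filter, but the symbol still exists in the net
                g.add_node(a)
                n_self += 1
                continue
            if g.has_edge(a, b):
                g.edges[a, b]["sources"].add(source)
            else:
                g.add_edge(a, b, sources={source})
    logger.info(
        "merged %d interaction rows into %d edges over %d nodes (%d self-loops removed)",
        n_rows, g.number_of_edges(), g.number_of_nodes(), n_self,
    )
    return g


@dataclass
class InducedSubgraph:
    """Restriction of the interactome to a disease feature set.

    ``members`` are the features present in the parent network; ``retained``
    is populated by :func:`drop_isolated` with the members having at least one
    edge to another member; ``dropped_absent`` are features missing from the
    parent node set entirely.
    """

    parent: nx.Graph
    members: set[str]
    graph: nx.Graph
    retained: set[str] = field(default_factory=set)
    dropped_isolated: set[str] = field(default_factory=set)
    dropped_absent: set[str] = field(default_factory=set)

    def membership_frame(self) -> pd.DataFrame:
        rows = []
        for sym in sorted(self.members | self.dropped_absent):
            if sym in self.retained:
                status, reason = True, ""
            elif sym in self.dropped_isolated:
                status, reason = False, "isolated"
            else:
                status, reason = False, "absent_from_network"
            rows.append({"symbol": sym, "retained": status, "drop_reason": reason})
        return pd.DataFrame(rows, columns=["symbol", "retained", "drop_reason"])


def induce_subgraph(net: nx.Graph, features: Iterable[str]) -> InducedSubgraph:
    """Induce the subgraph of ``net`` on ``features``.

    Neighbours that are not themselves features are NOT added: the disease
    subgraph is over disease features only.
    """
    features = set(features)
    if not features:
        logger.warning("induce_subgraph called with empty feature set")
    members = features & set(net.nodes)
    sub = net.subgraph(members).copy()
    return InducedSubgraph(
        parent=net,
        members=members,
        graph=sub,
        retained=set(members),
        dropped_isolated=set(),
        dropped_absent=features - members,
    )


def drop_isolated(sub: InducedSubgraph) -> InducedSubgraph:
    """Apply the connectivity filter: keep members with >= 1 edge to another
    member. One pass suffices — removing a degree-0 node cannot isolate any
    other node."""
    retained = {n for n in sub.members if n in sub.graph and sub.graph.degree(n) > 0}
    dropped = sub.members - retained
    if dropped:
        logger.info("connectivity filter dropped %d isolated members", len(dropped))
    return InducedSubgraph(
        parent=sub.parent,
        members=set(sub.members),
        graph=sub.graph.subgraph(retained).copy(),
        retained=retained,
        dropped_isolated=dropped,
        dropped_absent=set(sub.dropped_absent),
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

_FORMATS = {"sif", "graphml", "tsv"}


def export_network(graph: nx.Graph | InducedSubgraph, path: str | Path, fmt: str = "tsv") -> Path:
    """Write a network as SIF ("A interacts B"), GraphML, or edge TSV.

    The TSV round-trips through :func:`load_edges` + :func:`merge_networks`
    to the identical node and edge sets.
    """
    if isinstance(graph, InducedSubgraph):
        graph = graph.graph
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown export format {fmt!r}; expected one of {sorted(_FORMATS)}")
    path = Path(path)
    if fmt == "graphml":
        g = nx.Graph()
        g.add_nodes_from(graph.nodes)
        for a, b, data in graph.edges(data=True):
            g.add_edge(a, b, sources=";".join(sorted(data.get("sources", {"unspecified"}))))
        nx.write_graphml(g, path)
        return path
    with open(path, "w") as fh:
        if fmt == "sif":
            for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
                fh.write(f"{a}\tinteracts\t{b}\n")
        else:
            fh.write("interactor_a\tinteractor_b\tsource_db\n")
            for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
                sources = ";".join(sorted(graph.edges[a, b].get("sources", {"unspecified"})))
                fh.write(f"{a}\t{b}\t{sources}\n")
    return path
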