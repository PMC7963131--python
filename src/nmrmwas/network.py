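"""Reaction-pair metabolic subnetworks.

Compounds are nodes; main reaction pairs (substrate-product pairs) are
undirected edges.  The subnetwork connecting the phenotype-associated
metabolites is the union, over every unordered hit pair, of ALL nodes and
edges lying on ANY shortest path between the pair.  Nodes are flagged hit
or intermediate and carry the direction of association (direct / inverse /
none) for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd


def build_adjacency(reaction_pairs) -> nx.Graph:
    """Undirected simple compound graph from an iterable of (a, b) pairs.

    Duplicate edges are merged; self-loop rows are dropped with a warning.
    """
    pairs = list(reaction_pairs)
    if not pairs:
        raise ValueError("empty reaction-pair list")
    g = nx.Graph()
    dropped = 0
    for a, b in pairs:
        if a == b:
            dropped += 1
            continue
        g.add_edge(a, b)
    if dropped:
        warnings.warn(f"dropped {dropped} self-loop reaction pair(s)")
    return g


def read_edge_list(path) -> nx.Graph:
    """Two-column TSV of compound identifiers (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("expected two tab-separated columns")
    pairs = list(df.iloc[:, :2].itertuples(index=False, name=None))
    # tolerate a conventional header line
    header = (str(pairs[0][0]).lower(), str(pairs[0][1]).lower())
    if header in (("compound_a", "compound_b"), ("source", "target"),
                  ("from", "to")):
        pairs = pairs[1:]
    return build_adjacency(pairs)


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


@dataclass
class SubnetworkResult:
    graph: nx.Graph                       # nodes carry role/direction attrs
    hits: list
    unreachable_pairs: list = field(default_factory=list)
    unmapped_hits: list = field(default_factory=list)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def role_of(self, node) -> str:
        return self.graph.nodes[node]["role"]

    def summary(self) -> str:
        inter = sum(1 for n in self.graph.nodes
                    if self.graph.nodes[n]["role"] == "intermediate")
        return (f"subnetwork: {self.graph.number_of_nodes()} compounds "
                f"({len(self.hits) - len(self.unmapped_hits)} hits, {inter} "
                f"intermediates), {self.graph.number_of_edges()} edges; "
                f"{len(self.unreachable_pairs)} unreachable pair(s), "
                f"{len(self.unmapped_hits)} unmapped hit(s)")


def shortest_path_subnetwork(graph: nx.Graph, hits, directions=None) -> SubnetworkResult:
    """Union of all shortest paths between every pair of hit compounds.

    A node v lies on a shortest a-b path iff d(a,v) + d(v,b) = d(a,b); an
    edge (u,w) iff d(a,u) + 1 + d(w,b) = d(a,b) in either orientation.
    Pairs in different components are recorded in ``unreachable_pairs``
    (per-component subnetworks are still emitted); hits absent from the
    graph go to ``unmapped_hits``.
    """
    directions = dict(directions or {})
    hits = list(dict.fromkeys(hits))  # dedupe, keep order
    mapped = [h for h in hits if h in graph]
    unmapped = [h for h in hits if h not in graph]
    if len(mapped) < 2:
        raise ValueError("need at least 2 hits mapped to the graph")

    dist = {h: nx.single_source_shortest_path_length(graph, h) for h in mapped}
    sub = nx.Graph()
    unreachable = []
    for i in range(len(mapped)):
        for j in range(i + 1, len(mapped)):
            a, b = mapped[i], mapped[j]
            da, db = dist[a], dist[b]
            if b not in da:
                unreachable.append((a, b))
                continue
            d = da[b]
            on_path = [v for v in da
                       if v in db and da[v] + db[v] == d]
            sub.add_nodes_from(on_path)
            for u in on_path:
                for w in graph[u]:
                    if (w in db and u in da and w in da
                            and da[u] + 1 + db[w] == d):
                        sub.add_edge(u, w)
    sub.add_nodes_from(mapped)  # isolated hits (e.g. all pairs unreachable)
    hit_set = set(mapped)
    for n in sub.nodes:
        sub.nodes[n]["role"] = "hit" if n in hit_set else "intermediate"
        sub.nodes[n]["direction"] = str(directions.get(n, "none"))
    return SubnetworkResult(sub, hits, unreachable, unmapped)


def export_graph(result: SubnetworkResult, path, format: str = "graphml") -> None:
    """Write the subnetwork as GraphML, DOT, or a TSV edge list with a
    sidecar node table; node role and direction attributes round-trip."""
    g = result.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty subnetwork")
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "dot":
        colour = {"direct": "orange", "inverse": "blue", "none": "grey"}
        with open(path, "w") as fh:
            fh.write("graph metabonetwork {\n")
            for n in sorted(g.nodes):
                a = g.nodes[n]
                shape = "box" if a["role"] == "hit" else "ellipse"
                fh.write(f'  "{n}" [role="{a["role"]}" direction="{a["direction"]}"'
                         f' shape={shape} color={colour[a["direction"]]}];\n')
            for u, v in sorted(tuple(sorted(e)) for e in g.edges):
                fh.write(f'  "{u}" -- "{v}";\n')
            fh.write("}\n")
    elif format == "tsv":
        write_edge_list(g, path)
        nodes = pd.DataFrame(
            [(n, g.nodes[n]["role"], g.nodes[n]["direction"])
             for n in sorted(g.nodes)],
            columns=["compound", "role", "direction"])
        nodes.to_csv(str(path) + ".nodes.tsv", sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def import_graphml(path) -> SubnetworkResult:
    g = nx.read_graphml(path)
    hits = [n for n in g.nodes if g.nodes[n].get("role") == "hit"]
    return SubnetworkResult(nx.Graph(g), hits)
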