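"""Bipartite metabolite-protein network reconstruction and export.

Metabolite-protein associations from the metabolomics evidence are turned
into a bipartite graph (metabolites on one side, their associated enzymes/
transporters on the other, edges labelled with the protein's role).  The
network is exported as SIF or GraphML for downstream viewers; both formats
round-trip losslessly through the importers here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import networkx as nx

from .types import MetaboliteAssociation, Role

PathLike = Union[str, Path]

#: Export name prefixes that disambiguate a metabolite from a protein sharing
#: the same label (the two namespaces are otherwise free to collide).
METABOLITE_PREFIX = "m:"
PROTEIN_PREFIX = "p:"


@dataclass
class BipartiteNetwork:
    """A bipartite metabolite-protein graph with role-labelled edges."""

    metabolite_nodes: set[str] = field(default_factory=set)
    protein_nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str, Role]] = field(default_factory=set)

    def validate(self) -> None:
        """Check bipartiteness invariants; raises ValueError on violation.

        The two node classes live in separate namespaces (a metabolite and a
        protein may share a label; exports disambiguate with class prefixes),
        so bipartiteness means every edge runs from a registered metabolite
        node to a registered protein node.
        """
        for met, prot, _ in self.edges:
            if met not in self.metabolite_nodes:
                raise ValueError(f"edge endpoint {met!r} not a metabolite node")
            if prot not in self.protein_nodes:
                raise ValueError(f"edge endpoint {prot!r} not a protein node")


def build_network(assocs: Iterable[MetaboliteAssociation]) -> BipartiteNetwork:
    """Build the bipartite network; node sets are exactly the edge endpoints."""
    net = BipartiteNetwork()
    for a in assocs:
        net.metabolite_nodes.add(a.metabolite)
        net.protein_nodes.add(a.protein)
        net.edges.add((a.metabolite, a.protein, a.role))
    return net


def to_networkx(net: BipartiteNetwork) -> nx.MultiGraph:
    """Render as a networkx MultiGraph (parallel edges keep distinct roles)."""
    g = nx.MultiGraph()
    for m in net.metabolite_nodes:
        g.add_node(METABOLITE_PREFIX + m, label=m, **{"class": "metabolite"})
    for p in net.protein_nodes:
        g.add_node(PROTEIN_PREFIX + p, label=p, **{"class": "protein"})
    for m, p, role in sorted(net.edges):
        g.add_edge(METABOLITE_PREFIX + m, PROTEIN_PREFIX + p, role=role.value)
    return g


def network_stats(net: BipartiteNetwork) -> dict:
    """Node/edge counts, degree extrema and connected-component count."""
    g = to_networkx(net)
    met_degrees = [g.degree(METABOLITE_PREFIX + m) for m in net.metabolite_nodes]
    prot_degrees = [g.degree(PROTEIN_PREFIX + p) for p in net.protein_nodes]
    return {
        "n_metabolites": len(net.metabolite_nodes),
        "n_proteins": len(net.protein_nodes),
        "n_edges": len(net.edges),
        "max_metabolite_degree": max(met_degrees, default=0),
        "min_metabolite_degree": min(met_degrees, default=0),
        "max_protein_degree": max(prot_degrees, default=0),
        "min_protein_degree": min(prot_degrees, default=0),
        "n_components": nx.number_connected_components(g) if g.number_of_nodes() else 0,
    }


def export_network(net: BipartiteNetwork, path: PathLike, format: str = "SIF") -> None:
    """Write the network as SIF or GraphML.

    SIF lines are ``metabolite<TAB>role<TAB>protein`` with the role lowercased
    and one line per (pair, role); GraphML carries a ``class`` node attribute
    and ``role`` edge attribute, with parallel multi-role edges preserved.
    """
    fmt = format.strip().upper()
    if fmt == "SIF":
        lines = [
            f"{METABOLITE_PREFIX}{m}\t{role.value.lower()}\t{PROTEIN_PREFIX}{p}"
            for m, p, role in sorted(net.edges)
        ]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "GRAPHML":
        nx.write_graphml(to_networkx(net), str(path))
    else:
        raise ValueError(f"unknown export format {format!r} (expected SIF or GRAPHML)")


def _strip(node: str, kind: str) -> str:
    prefix = METABOLITE_PREFIX if kind == "metabolite" else PROTEIN_PREFIX
    if not node.startswith(prefix):
        raise ValueError(f"node {node!r} lacks the {kind} prefix {prefix!r}")
    return node[len(prefix):]


def import_network(path: PathLike, format: str = "SIF") -> BipartiteNetwork:
    """Re-import a network written by :func:`export_network`."""
    fmt = format.strip().upper()
    net = BipartiteNetwork()
    if fmt == "SIF":
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            m_node, role_token, p_node = line.split("\t")
            m, p = _strip(m_node, "metabolite"), _strip(p_node, "protein")
            net.metabolite_nodes.add(m)
            net.protein_nodes.add(p)
            net.edges.add((m, p, Role(role_token.upper())))
    elif fmt == "GRAPHML":
        g = nx.read_graphml(str(path))
        labels = {}
        for node, data in g.nodes(data=True):
            label = data.get("label", node)
            labels[node] = label
            if data["class"] == "metabolite":
                net.metabolite_nodes.add(label)
            else:
                net.protein_nodes.add(label)
        for u, v, data in g.edges(data=True):
            if u.startswith(PROTEIN_PREFIX):
                u, v = v, u
            net.edges.add((labels[u], labels[v], Role(data["role"])))
    else:
        raise ValueError(f"unknown import format {format!r} (expected SIF or GRAPHML)")
    net.validate()
    return net
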