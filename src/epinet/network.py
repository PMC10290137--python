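"""Chaperome-layered interaction network assembly and topology metrics.

The network is the subgraph of the merged PPI database induced on the
proteins detected by the bait(s), the documented interactors of the bait
chaperones, and the chaperome members present in the database. Nodes are
classified into three layers — ``chaperome``, ``direct_interactor``
(non-chaperome node adjacent to a chaperome node) and ``indirect`` — and
edges carry one of three emphasis weights:

* chaperome-chaperome: 10000
* chaperome-non-chaperome: 100
* everything else (including direct-direct): 1

The weights encode the layering for downstream layout/emphasis; the
topology statistics (average local clustering coefficient, Freeman degree
centralization, density) are computed on the unweighted simple graph.
Documented interactors that no bait detected keep the boolean ``reduced``
attribute, the semantic equivalent of drawing them as dots.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping

import networkx as nx

from epinet.errors import FormatError, StructuralError
from epinet.ppi import MergedPPIDatabase

__all__ = [
    "WEIGHT_CORE",
    "WEIGHT_SHELL",
    "WEIGHT_OUTER",
    "build_network",
    "assign_edge_weights",
    "compute_topology",
    "export_graph",
    "import_graph",
]

logger = logging.getLogger(__name__)

WEIGHT_CORE = 10000
WEIGHT_SHELL = 100
WEIGHT_OUTER = 1


def build_network(
    db: MergedPPIDatabase,
    detected: Mapping[str, Mapping],
    chaperome: set[str],
    documented_interactors: set[str] | None = None,
) -> nx.Graph:
    """Assemble the annotated network.

    Parameters
    ----------
    db : MergedPPIDatabase
        The merged human PPI reference.
    detected : mapping protein_id -> attributes
        Proteins identified by at least one bait; values may carry
        ``detected_by`` (iterable of bait labels) and ``grade``.
    chaperome : set
        Chaperome membership list (must be non-empty: the layering is
        undefined without a core).
    documented_interactors : set, optional
        Documented interactors of the bait chaperones to include even when
        not detected (they get ``reduced=True``). Defaults to the database
        neighbors of the chaperome members.

    Returns
    -------
    networkx.Graph with node attributes ``is_chaperome, node_class,
    detected_by, grade, reduced`` and no edge weights yet (see
    :func:`assign_edge_weights`). Nodes without any induced edge are kept
    as isolates (their count is logged).
    """
    if not chaperome:
        raise StructuralError("chaperome set is empty: the network layering is undefined")
    if documented_interactors is None:
        documented_interactors = db.get_interactors(set(chaperome))

    node_ids = set(detected) | set(documented_interactors) | (set(chaperome) & db.nodes)
    g = nx.Graph()
    for node in sorted(node_ids):
        info = detected.get(node, {})
        detected_by = sorted(info.get("detected_by", ())) if node in detected else []
        g.add_node(
            node,
            is_chaperome=node in chaperome,
            detected_by="|".join(detected_by),
            grade=str(info.get("grade", "")) if node in detected else "",
            reduced=(node not in detected) and (node not in chaperome),
        )
    for (a, b), sources in db.edges.items():
        if a in node_ids and b in node_ids:
            g.add_edge(a, b, provenance="|".join(sorted(sources)))

    n_isolates = sum(1 for v in g.nodes if g.degree(v) == 0)
    if n_isolates:
        logger.info("network has %d isolate nodes (no induced PPI edge)", n_isolates)

    for node in g.nodes:
        if g.nodes[node]["is_chaperome"]:
            cls = "chaperome"
        elif any(g.nodes[nb]["is_chaperome"] for nb in g.neighbors(node)):
            cls = "direct_interactor"
        else:
            cls = "indirect"
        g.nodes[node]["node_class"] = cls
    return g


def assign_edge_weights(net: nx.Graph) -> nx.Graph:
    """Assign the three-tier emphasis weights in place (and return the net).

    Requires node classes to be present; raises on unclassified nodes.
    """
    for node in net.nodes:
        if "node_class" not in net.nodes[node]:
            raise StructuralError(f"node {node} has no class; run build_network first")
    for a, b in net.edges:
        a_chap = net.nodes[a]["node_class"] == "chaperome"
        b_chap = net.nodes[b]["node_class"] == "chaperome"
        if a_chap and b_chap:
            w = WEIGHT_CORE
        elif a_chap or b_chap:
            w = WEIGHT_SHELL
        else:
            w = WEIGHT_OUTER
        net.edges[a, b]["weight"] = w
    return net


def degree_centralization(net: nx.Graph) -> float:
    """Freeman degree centralization: sum(d_max - d_i) / ((n-1)(n-2)).

    1 for a star, 0 for any degree-regular graph. Undefined for n < 3
    (reported as 0 with a warning).
    """
    n = net.number_of_nodes()
    if n < 3:
        warnings.warn("degree centralization undefined for n < 3; reporting 0.0")
        return 0.0
    degrees = [d for _, d in net.degree()]
    d_max = max(degrees)
    return sum(d_max - d for d in degrees) / ((n - 1) * (n - 2))


def compute_topology(net: nx.Graph, weighted: bool = False) -> dict:
    """Topology report of the (simple) graph.

    Average local clustering coefficient (nodes of degree < 2 contribute
    0), global transitivity for reference, Freeman degree centralization,
    density and a degree summary. ``weighted=True`` additionally reports a
    weight-aware average clustering for users who want the emphasis weights
    reflected; the headline metrics stay unweighted.
    """
    n = net.number_of_nodes()
    m = net.number_of_edges()
    degrees = sorted(d for _, d in net.degree())
    report = {
        "n_nodes": n,
        "n_edges": m,
        "average_clustering": nx.average_clustering(net) if n else 0.0,
        "transitivity": nx.transitivity(net) if n else 0.0,
        "degree_centralization": degree_centralization(net) if n else 0.0,
        "density": nx.density(net) if n else 0.0,
        "degree_min": degrees[0] if degrees else 0,
        "degree_median": float(degrees[len(degrees) // 2]) if degrees else 0.0,
        "degree_max": degrees[-1] if degrees else 0,
    }
    if weighted and m:
        report["average_clustering_weighted"] = nx.average_clustering(net, weight="weight")
    return report


def export_graph(net: nx.Graph, path: str | Path, format: str = "graphml") -> Path:
    """Write the network losslessly as GraphML or a TSV edge list.

    The TSV edge list keeps ``id_a, id_b, weight`` (sorted within and
    across rows); GraphML keeps all node and edge attributes.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "graphml":
        nx.write_graphml(net, path, named_key_ids=True, edge_id_from_attribute=None)
    elif format == "tsv_edgelist":
        lines = ["id_a\tid_b\tweight"]
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            lines.append(f"{a}\t{b}\t{net.edges[a, b].get('weight', '')}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise FormatError(f"unknown export format {format!r}")
    return path


def import_graph(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Read a network previously written by :func:`export_graph`."""
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "tsv_edgelist":
        g = nx.Graph()
        lines = path.read_text().splitlines()
        for line in lines[1:]:
            if not line.strip():
                continue
            a, b, w = line.split("\t")
            g.add_edge(a, b, weight=int(w) if w else None)
        return g
    raise FormatError(f"unknown import format {format!r}")
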