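"""Assemble the weighted heterogeneous circRNA–disease network.

circRNA–circRNA edges fuse the two similarity views:

    CircWeight(i, j) = (FnSim(i, j) + ExSim(i, j)) / 2   if ExSim(i, j) > 0
                       FnSim(i, j)                       otherwise

circRNA–disease edges carry weight 1 exactly for curated associations.
The network is undirected; disease–disease edges never exist; zero-weight
pairs produce no edge (indistinguishable from no edge under the walk).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from precda.errors import ParameterError, PrecdaError
from precda.expression import ExpressionSimilarityMatrix
from precda.functional import FunctionalSimilarityMatrix
from precda.ingest import AssociationDB

CIRC = "circrna"
DISEASE = "disease"


def circ_weight(fnsim: float, exsim: float) -> float:
    """Edge weight between two circRNAs: mean of the two similarities when
    expression evidence survives the τ filter, functional similarity alone
    otherwise."""
    if not (0 <= fnsim <= 1):
        raise ParameterError(f"functional similarity {fnsim} outside [0, 1]")
    if not (0 <= exsim <= 1):
        raise ParameterError(f"expression similarity {exsim} outside [0, 1]")
    if exsim > 0:
        return (fnsim + exsim) / 2.0
    return fnsim


def circdis_weight(c: str, dis: str, assoc: AssociationDB) -> int:
    """1 iff the (circRNA, disease) pair is curated, else 0."""
    return 1 if (c, dis) in assoc.pairs else 0


def assemble_network(
    fnsim: FunctionalSimilarityMatrix,
    exsim: ExpressionSimilarityMatrix | None,
    assoc: AssociationDB,
) -> nx.Graph:
    """Build the heterogeneous network over assoc's circRNAs and diseases.

    ``exsim`` may be None (cosine-only ablation) or cover only a subset of
    circRNAs — uncovered pairs count as expression similarity 0. Isolated
    nodes are retained. Node attribute ``kind`` distinguishes circRNA from
    disease nodes; edge attribute ``kind`` is "cc" or "cd".
    """
    circ_ids = sorted(fnsim.circ_ids)
    missing = [c for c in sorted(assoc.circ_ids) if c not in fnsim]
    if missing:
        raise PrecdaError(f"circRNAs absent from functional similarity: {missing}")

    g = nx.Graph()
    for c in circ_ids:
        g.add_node(c, kind=CIRC)
    for d in sorted(assoc.disease_ids):
        g.add_node(d, kind=DISEASE)

    for i, ci in enumerate(circ_ids):
        for cj in circ_ids[i + 1 :]:
            fn = fnsim.loc(ci, cj)
            ex = 0.0
            if exsim is not None and ci in exsim and cj in exsim:
                ex = exsim.loc(ci, cj)
                if not (ex == 0.0 or ex >= (exsim.tau or 0)):
                    raise PrecdaError("expression similarity matrix is not thresholded")
            w = circ_weight(fn, ex)
            if w > 0:
                g.add_edge(ci, cj, weight=w, kind="cc")

    for c, d in assoc.pairs:
        g.add_edge(c, d, weight=1.0, kind="cd")
    return g


def write_network(g: nx.Graph, path: str | Path) -> None:
    """Serialise as a TSV edge list (node_a, node_b, weight, edge_type)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# node_a\tnode_b\tweight\tedge_type\n")
        for a, b, data in sorted(g.edges(data=True)):
            if data["kind"] == "cd" and g.nodes[a]["kind"] == DISEASE:
                a, b = b, a  # cd rows always list the circRNA first
            fh.write(f"{a}\t{b}\t{data['weight']!r}\t{data['kind']}\n")
        for node, data in sorted(g.nodes(data=True)):
            if g.degree(node) == 0:
                fh.write(f"{node}\t.\t0\tisolated_{data['kind']}\n")


def read_network(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b, w, kind = line.split("\t")
            if kind.startswith("isolated_"):
                g.add_node(a, kind=kind.removeprefix("isolated_"))
                continue
            if kind == "cd":
                # curated association: first column circRNA, second disease
                g.add_node(a, kind=CIRC)
                g.add_node(b, kind=DISEASE)
            else:
                g.add_node(a, kind=CIRC)
                g.add_node(b, kind=CIRC)
            g.add_edge(a, b, weight=float(w), kind=kind)
    return g
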