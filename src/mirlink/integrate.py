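"""Integration of sparse-CCA-selected nodes with estimated network links.

The final reported network keeps exactly the miRNAs and mRNAs selected by
the sparse supervised CCA, annotated with their loading weights, plus the
links of a source network (SPACE partial correlations or the A*-lasso DAG)
whose *both* endpoints are selected nodes.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cca import CanonicalPair

__all__ = ["IntegratedNetwork", "integrate", "compare_networks"]

_EDGE_COLS = ["node_i", "node_j", "weight", "sign", "directed", "source"]


@dataclass
class IntegratedNetwork:
    """Selected nodes with loadings plus the surviving links."""

    nodes: pd.DataFrame  # feature_id, kind, loading
    edges: pd.DataFrame  # node_i, node_j, weight, sign, directed, source
    provenance: dict = field(default_factory=dict)

    @property
    def node_ids(self) -> set[str]:
        return set(self.nodes["feature_id"])

    def edge_pairs(self) -> set[frozenset]:
        """Edges as unordered node-id pairs (direction ignored)."""
        return {frozenset((a, b)) for a, b in zip(self.edges["node_i"], self.edges["node_j"])}

    # -- exports ---------------------------------------------------------
    def to_graphml(self, path) -> None:
        g = nx.DiGraph() if self.edges.get("directed", pd.Series(dtype=bool)).any() else nx.Graph()
        for _, r in self.nodes.iterrows():
            g.add_node(r["feature_id"], kind=r["kind"], loading=float(r["loading"]))
        for _, r in self.edges.iterrows():
            g.add_edge(r["node_i"], r["node_j"], weight=float(r["weight"]),
                       sign=int(r["sign"]), source=str(r["source"]))
        nx.write_graphml(g, path)

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        payload = {
            "nodes": self.nodes.to_dict(orient="records"),
            "edges": self.edges[_EDGE_COLS].to_dict(orient="records"),
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


def _edges_of(net) -> pd.DataFrame:
    for attr in ("edges_", "edges"):
        e = getattr(net, attr, None)
        if isinstance(e, pd.DataFrame):
            return e
    raise TypeError(f"object of type {type(net).__name__} carries no edge table")


def integrate(pair: CanonicalPair, net, provenance: dict | None = None) -> IntegratedNetwork:
    """Node-induced subgraph of ``net`` on the sparse-CCA-selected features.

    ``net`` may be a fitted network estimator, a :class:`DagModel`, or an
    already-integrated network (in which case the operation is idempotent
    for the same pair).  An empty selection yields an empty network.
    """
    sel_x = pair.selected_x_ids
    sel_y = pair.selected_y_ids
    selected = set(sel_x) | set(sel_y)

    nodes = pd.DataFrame(
        {
            "feature_id": sel_x + sel_y,
            "kind": ["miRNA"] * len(sel_x) + ["mRNA"] * len(sel_y),
            "loading": [pair.u[i] for i in pair.selected_x]
            + [pair.v[i] for i in pair.selected_y],
        }
    )

    edges = _edges_of(net)
    known = set(edges["node_i"]) | set(edges["node_j"]) if len(edges) else set()
    all_ids = set(getattr(net, "feature_names_", [])) or set(
        getattr(net, "node_names", [])
    ) or known
    if all_ids and selected and not (selected & all_ids) and len(edges):
        raise ValueError("feature identifier spaces of the pair and network do not match")

    if len(edges):
        keep = edges["node_i"].isin(selected) & edges["node_j"].isin(selected)
        edges = edges.loc[keep].reset_index(drop=True)
    cols = [c for c in _EDGE_COLS if c in edges.columns] or _EDGE_COLS
    edges = edges.reindex(columns=cols if len(edges) else _EDGE_COLS)
    return IntegratedNetwork(nodes=nodes, edges=edges, provenance=provenance or {})


def compare_networks(a: IntegratedNetwork, b: IntegratedNetwork) -> dict:
    """Overlap report between two integrated networks.

    Edges are matched as unordered pairs (A*-lasso directions ignored).
    Reported: edge counts, shared edges, shared miRNA-mRNA (cross-set)
    edges, and the sign-agreement fraction among shared edges.
    """
    pa, pb = a.edge_pairs(), b.edge_pairs()
    shared = pa & pb
    kind = dict(zip(a.nodes["feature_id"], a.nodes["kind"]))
    kind.update(zip(b.nodes["feature_id"], b.nodes["kind"]))

    def is_cross(pairset) -> bool:
        ids = sorted(pairset)
        return kind.get(ids[0]) != kind.get(ids[1])

    def sign_of(net: IntegratedNetwork, pairset) -> int | None:
        for _, r in net.edges.iterrows():
            if frozenset((r["node_i"], r["node_j"])) == pairset:
                return int(r["sign"])
        return None

    agree = total = 0
    for e in shared:
        sa, sb = sign_of(a, e), sign_of(b, e)
        if sa is not None and sb is not None:
            total += 1
            agree += int(sa == sb)
    return {
        "n_edges_a": len(pa),
        "n_edges_b": len(pb),
        "n_shared": len(shared),
        "n_shared_cross": sum(is_cross(e) for e in shared),
        "sign_agreement": (agree / total) if total else float("nan"),
    }
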