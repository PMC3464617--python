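"""Length-scale and residue-class subnetworks of a contact map.

A :class:`NetworkSpec` fixes three orthogonal filters:

* range: all-range ``arn`` (x > 0), long-range ``lrn`` (x > 10), or
  short-range ``srn`` (0 < x <= 10), where x = |i - j| is the sequence
  separation of the two residues;
* class: all residues ``an``, hydrophobic ``bn``, hydrophilic ``in``,
  charged ``cn`` — the class filter restricts the *node* set, so an edge
  survives only if both endpoints belong to the class;
* ``i_min``: the percent threshold; an edge exists iff I_ij > i_min
  (strict inequality).

Nodes isolated by the filters are kept in the node set: normalized
largest-component sizes always use the full residue count of the protein.
"""

from __future__ import annotations

from dataclasses import dataclass
import networkx as nx
import numpy as np

from .contact_network import ContactMap

__all__ = [
    "RANGE_FILTERS",
    "CLASS_FILTERS",
    "NetworkSpec",
    "ResidueGraph",
    "build_graph",
    "connected_components",
]

RANGE_FILTERS = ("arn", "lrn", "srn")
CLASS_FILTERS = ("an", "bn", "in", "cn")

_CLASS_OF_FILTER = {"bn": "B", "in": "I", "cn": "C"}


@dataclass(frozen=True)
class NetworkSpec:
    """One (range, class, i_min) slice of a contact map."""

    range_filter: str = "arn"
    class_filter: str = "an"
    i_min: float = 0.0

    def __post_init__(self) -> None:
        if self.range_filter not in RANGE_FILTERS:
            raise ValueError(f"range_filter must be one of {RANGE_FILTERS}")
        if self.class_filter not in CLASS_FILTERS:
            raise ValueError(f"class_filter must be one of {CLASS_FILTERS}")
        if self.i_min < 0:
            raise ValueError("i_min must be >= 0")

    @property
    def slice_label(self) -> str:
        return f"{self.range_filter.upper()}-{self.class_filter.upper()}"


@dataclass(frozen=True)
class ResidueGraph:
    """An unweighted graph realized from a ContactMap under a NetworkSpec.

    ``graph`` is a networkx Graph whose nodes are residue ``seq_index``
    values (1-based) with a ``res_class`` attribute, and whose edges carry
    the underlying ``strength`` (I_ij).  ``n_total`` is the full residue
    count of the protein, used as the normalization denominator for
    component sizes irrespective of the class filter.
    """

    spec: NetworkSpec
    graph: nx.Graph
    n_total: int
    structure_id: str = ""

    @property
    def nodes(self) -> tuple[int, ...]:
        return tuple(sorted(self.graph.nodes))

    @property
    def edges(self) -> tuple[tuple[int, int], ...]:
        return tuple(sorted(tuple(sorted(e)) for e in self.graph.edges))

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_strength(self, i: int, j: int) -> float:
        return self.graph.edges[i, j]["strength"]

    def classes(self) -> dict[int, str]:
        return dict(self.graph.nodes(data="res_class"))

    @property
    def adjacency(self) -> np.ndarray:
        """Symmetric 0/1 matrix over the retained nodes (sorted order)."""
        order = self.nodes
        return nx.to_numpy_array(self.graph, nodelist=order, weight=None)

    def to_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {self.structure_id} {self.spec.slice_label} "
                     f"i_min={self.spec.i_min:g}\n")
            fh.write("i\tj\tI_ij\n")
            for i, j in self.edges:
                fh.write(f"{i}\t{j}\t{self.edge_strength(i, j):.6g}\n")


def _range_mask(sep: np.ndarray, range_filter: str) -> np.ndarray:
    if range_filter == "arn":
        return sep > 0
    if range_filter == "lrn":
        return sep > 10
    return (sep > 0) & (sep <= 10)


def build_graph(cm: ContactMap, spec: NetworkSpec) -> ResidueGraph:
    """Realize the unweighted graph of one (range, class, i_min) slice."""
    classes = cm.classes
    keep_class = _CLASS_OF_FILTER.get(spec.class_filter)
    node_idx = [
        i for i in range(cm.L)
        if keep_class is None or classes[i] == keep_class
    ]
    g = nx.Graph()
    g.add_nodes_from((i + 1, {"res_class": classes[i]}) for i in node_idx)

    mask = _range_mask(cm.sep, spec.range_filter) & (cm.strength > spec.i_min)
    keep = np.zeros(cm.L, dtype=bool)
    keep[node_idx] = True
    mask &= keep[:, None] & keep[None, :]
    ii, jj = np.nonzero(np.triu(mask, k=1))
    g.add_edges_from(
        (int(i) + 1, int(j) + 1, {"strength": float(cm.strength[i, j])})
        for i, j in zip(ii, jj)
    )
    return ResidueGraph(spec=spec, graph=g, n_total=cm.L,
                        structure_id=cm.structure_id)


def connected_components(g: ResidueGraph) -> list[frozenset[int]]:
    """Maximal connected node sets, largest first.

    Ties in size are broken by the smallest member index so the order is
    deterministic.
    """
    comps = [frozenset(c) for c in nx.connected_components(g.graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))
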