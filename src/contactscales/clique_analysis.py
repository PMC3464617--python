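"""3-clique composition census and sequence-perimeter statistics.

Every triangle of a contact network is classified by the multiset of its
members' residue classes — hydrophobic (B), hydrophilic (I), charged (C) —
giving ten composition types.  Raw counts are not comparable across types
or proteins, so each count is normalized by the number of triples of that
composition the protein could form at all:

* XXX:  C(n_X, 3)
* XXY:  C(n_X, 2) * n_Y
* BCI:  n_B * n_I * n_C

The *perimeter* of a clique is the sum of the pairwise sequence
separations of its members, ``|a-b| + |b-c| + |a-c|`` — equivalently
``2 (max - min)`` — so a large perimeter means residues far apart along
the chain meet in space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .subnetworks import ResidueGraph

__all__ = [
    "CLIQUE_TYPES",
    "Clique3",
    "CliqueCensus",
    "enumerate_triangles",
    "clique_perimeter",
    "normalized_occurrence",
    "census",
]

#: fixed type order; also the deterministic tie-break order
CLIQUE_TYPES = ("BBB", "BBI", "BBC", "BII", "BCI", "BCC",
                "III", "CII", "CCI", "CCC")

#: (n_B, n_I, n_C) of the members -> canonical type name
_TYPE_OF_COMPOSITION = {
    (3, 0, 0): "BBB", (2, 1, 0): "BBI", (2, 0, 1): "BBC",
    (1, 2, 0): "BII", (1, 1, 1): "BCI", (1, 0, 2): "BCC",
    (0, 3, 0): "III", (0, 2, 1): "CII", (0, 1, 2): "CCI",
    (0, 0, 3): "CCC",
}


@dataclass(frozen=True)
class Clique3:
    """A triangle of residues, members sorted ascending by seq_index."""

    members: tuple[int, int, int]
    comp_type: str

    def __post_init__(self) -> None:
        a, b, c = self.members
        if not (a < b < c):
            raise ValueError("members must be three distinct ascending indices")
        if self.comp_type not in CLIQUE_TYPES:
            raise ValueError(f"unknown composition type {self.comp_type}")

    @property
    def perimeter(self) -> int:
        return clique_perimeter(self)


def clique_perimeter(c: Clique3 | tuple[int, int, int]) -> int:
    """Sum of pairwise sequence separations of the three members."""
    a, b, cc = c.members if isinstance(c, Clique3) else c
    return abs(a - b) + abs(b - cc) + abs(a - cc)


def _comp_type(classes: Mapping[int, str], members: tuple[int, int, int]) -> str:
    counts = [0, 0, 0]
    for m in members:
        counts["BIC".index(classes[m])] += 1
    return _TYPE_OF_COMPOSITION[tuple(counts)]


def enumerate_triangles(g: ResidueGraph) -> list[Clique3]:
    """All 3-cliques of the graph, each unordered triple exactly once.

    Edge-iterator algorithm: for every edge (u, v) with u < v, common
    neighbours w > v close a triangle; sorted by members.
    """
    graph = g.graph
    classes = g.classes()
    adj = {u: set(graph[u]) for u in graph}
    triangles: list[Clique3] = []
    for u, v in graph.edges():
        if u > v:
            u, v = v, u
        for w in adj[u] & adj[v]:
            if w > v:
                members = (u, v, w)
                triangles.append(
                    Clique3(members=members, comp_type=_comp_type(classes, members))
                )
    triangles.sort(key=lambda t: t.members)
    return triangles


def _denominator(comp_type: str, n_b: int, n_i: int, n_c: int) -> int:
    n = {"B": n_b, "I": n_i, "C": n_c}
    letters = sorted(comp_type)
    if letters[0] == letters[1] == letters[2]:
        return math.comb(n[letters[0]], 3)
    if len(set(letters)) == 3:
        return n_b * n_i * n_c
    # XXY: the repeated letter and the single one
    rep = letters[0] if letters[0] == letters[1] else letters[1]
    single = next(l for l in letters if l != rep)
    return math.comb(n[rep], 2) * n[single]


def normalized_occurrence(counts: Mapping[str, int],
                          class_counts: Mapping[str, int]) -> dict[str, float]:
    """Counts divided by the combinatorially possible triples per type.

    ``class_counts`` maps "B"/"I"/"C" to the number of residues of each
    class in the whole protein.  A type whose denominator is zero (too few
    residues of a class) gets 0; a count exceeding its denominator is an
    impossible census and raises.
    """
    n_b = int(class_counts.get("B", 0))
    n_i = int(class_counts.get("I", 0))
    n_c = int(class_counts.get("C", 0))
    if min(n_b, n_i, n_c) < 0:
        raise ValueError("class counts must be non-negative")
    out: dict[str, float] = {}
    for t in CLIQUE_TYPES:
        count = int(counts.get(t, 0))
        denom = _denominator(t, n_b, n_i, n_c)
        if count > denom:
            raise ValueError(
                f"{count} {t} cliques but only {denom} possible triples"
            )
        out[t] = count / denom if denom else 0.0
    return out


@dataclass(frozen=True)
class CliqueCensus:
    """Counts, normalized occurrences and perimeter means of the 10 types."""

    structure_id: str
    counts: dict[str, int]
    normalized: dict[str, float]
    mean_perimeter: dict[str, float]  # NaN for types with no clique
    dominant_type: str | None
    max_perimeter_type: str | None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def census(g: ResidueGraph,
           class_counts: Mapping[str, int] | None = None) -> CliqueCensus:
    """Full composition census of the triangles of a graph.

    Meant for all-residue (AN) graphs so mixed-composition cliques exist;
    ``class_counts`` defaults to the class tally of the graph's own node
    set.  ``dominant_type`` maximizes the normalized occurrence and
    ``max_perimeter_type`` the mean perimeter (over types that occur);
    ties resolve to the earlier type in the fixed order.
    """
    triangles = enumerate_triangles(g)
    if class_counts is None:
        tally = {"B": 0, "I": 0, "C": 0}
        for cls in g.classes().values():
            tally[cls] += 1
        class_counts = tally

    counts = {t: 0 for t in CLIQUE_TYPES}
    perims: dict[str, list[int]] = {t: [] for t in CLIQUE_TYPES}
    for tri in triangles:
        counts[tri.comp_type] += 1
        perims[tri.comp_type].append(tri.perimeter)
    normalized = normalized_occurrence(counts, class_counts)
    mean_perimeter = {
        t: (float(np.mean(v)) if v else math.nan) for t, v in perims.items()
    }

    dominant = None
    if triangles:
        dominant = max(CLIQUE_TYPES, key=lambda t: (normalized[t], -CLIQUE_TYPES.index(t)))
    occupied = [t for t in CLIQUE_TYPES if counts[t] > 0]
    max_perim = None
    if occupied:
        max_perim = max(occupied,
                        key=lambda t: (mean_perimeter[t], -CLIQUE_TYPES.index(t)))
    return CliqueCensus(
        structure_id=g.structure_id,
        counts=counts,
        normalized=normalized,
        mean_perimeter=mean_perimeter,
        dominant_type=dominant,
        max_perimeter_type=max_perim,
    )
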