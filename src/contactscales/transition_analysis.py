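"""Percolation-like transition of the largest connected component.

As the edge threshold ``i_min`` rises from 0 to 10 percent, edges drop out
of a contact subnetwork and the largest connected component (LCC) shrinks.
The profile of the normalized LCC size (node count over the *total*
residue count of the protein) against ``i_min`` characterizes the network:

* ``i_critical`` — the threshold at which the LCC first falls to half its
  size at ``i_min = 0``, linearly interpolated between grid points;
* the cooperativity index ``CI = A / B``, where A is the last threshold at
  which the LCC still holds at least ``start_frac`` (default 95%) of its
  initial size and B the first at which it has collapsed to at most
  ``end_frac`` (default 10%).  A sharp, cooperative collapse has A close
  to B and CI close to 1; a gradual one has CI near 0.

Profiles that never reach the relevant level on the grid yield the
``BEYOND_GRID`` sentinel (NaN), which the paired comparison excludes from
averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .contact_network import ContactMap
from .subnetworks import NetworkSpec, build_graph, connected_components

__all__ = [
    "BEYOND_GRID",
    "default_grid",
    "TransitionProfile",
    "transition_profile",
    "i_critical",
    "cooperativity_index",
    "compare_pairs",
]

#: sentinel for "the profile does not reach this level on the grid"
BEYOND_GRID = math.nan


def default_grid() -> np.ndarray:
    """The standard threshold grid: 0 to 10 percent in steps of 0.5."""
    return np.round(np.arange(0.0, 10.0 + 1e-9, 0.5), 10)


@dataclass(frozen=True)
class TransitionProfile:
    """Normalized LCC size as a function of i_min on a fixed grid."""

    grid: np.ndarray
    lcc_norm: np.ndarray
    range_filter: str
    class_filter: str
    structure_id: str = ""

    def __post_init__(self) -> None:
        if len(self.grid) == 0:
            raise ValueError("empty grid")
        if len(self.grid) != len(self.lcc_norm):
            raise ValueError("grid and lcc_norm length mismatch")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    @property
    def spec(self) -> tuple[str, str]:
        return (self.range_filter, self.class_filter)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {self.structure_id} "
                     f"{self.range_filter.upper()}-{self.class_filter.upper()}\n")
            fh.write("i_min\tlcc_norm\n")
            for x, y in zip(self.grid, self.lcc_norm):
                fh.write(f"{x:g}\t{y:.6g}\n")


def transition_profile(cm: ContactMap, range_filter: str = "arn",
                       class_filter: str = "an",
                       grid: Sequence[float] | None = None) -> TransitionProfile:
    """Profile the normalized LCC size of one subnetwork slice over a grid.

    The denominator is always the total residue count of the protein, also
    for class-restricted slices, so profiles of different slices of the
    same protein are directly comparable.
    """
    g = default_grid() if grid is None else np.asarray(list(grid), dtype=float)
    if g.size == 0:
        raise ValueError("empty grid")
    lcc = np.empty_like(g)
    for idx, i_min in enumerate(g):
        spec = NetworkSpec(range_filter=range_filter,
                           class_filter=class_filter, i_min=float(i_min))
        rg = build_graph(cm, spec)
        comps = connected_components(rg)
        lcc[idx] = (len(comps[0]) if comps else 0) / cm.L
    return TransitionProfile(grid=g, lcc_norm=lcc,
                             range_filter=range_filter,
                             class_filter=class_filter,
                             structure_id=cm.structure_id)


def i_critical(p: TransitionProfile) -> float:
    """Threshold at which the LCC first reaches half its initial size.

    Linear interpolation between the bracketing grid points removes the
    grid-step bias; an exact hit returns the grid value itself.  Returns
    ``BEYOND_GRID`` when the profile never falls to half on the grid.
    """
    target = p.lcc_norm[0] / 2.0
    below = np.nonzero(p.lcc_norm <= target)[0]
    if len(below) == 0:
        return BEYOND_GRID
    i = int(below[0])
    if i == 0 or p.lcc_norm[i] == target:
        return float(p.grid[i])
    y0, y1 = p.lcc_norm[i - 1], p.lcc_norm[i]
    x0, x1 = p.grid[i - 1], p.grid[i]
    return float(x0 + (x1 - x0) * (y0 - target) / (y0 - y1))


def cooperativity_index(p: TransitionProfile, start_frac: float = 0.95,
                        end_frac: float = 0.10) -> float:
    """Ratio A/B of transition onset to breakdown thresholds.

    A is the largest grid value at which the LCC still holds at least
    ``start_frac`` of its initial size; B the smallest at which it is down
    to at most ``end_frac``.  Returns ``BEYOND_GRID`` when the collapse is
    not complete on the grid or the profile starts empty.
    """
    if not (0.0 < end_frac < start_frac < 1.0):
        raise ValueError("need 0 < end_frac < start_frac < 1")
    base = p.lcc_norm[0]
    if base <= 0:
        return BEYOND_GRID
    onset = np.nonzero(p.lcc_norm >= start_frac * base)[0]
    breakdown = np.nonzero(p.lcc_norm <= end_frac * base)[0]
    if len(breakdown) == 0:
        return BEYOND_GRID
    a = float(p.grid[onset[-1]]) if len(onset) else float(p.grid[0])
    b = float(p.grid[breakdown[0]])
    if b == 0:
        return BEYOND_GRID
    return a / b


def compare_pairs(profiles_a: Iterable[TransitionProfile],
                  profiles_b: Iterable[TransitionProfile]) -> pd.DataFrame:
    """Compare i_critical between two sets of profiles, slice by slice.

    Both sets must cover the same (range, class) slices.  Per slice the
    table reports the count, mean, min and max of the defined i_critical
    values of each set and the difference of means (set A minus set B).
    """
    pa, pb = list(profiles_a), list(profiles_b)
    if not pa or not pb:
        raise ValueError("both profile sets must be non-empty")
    specs_a = {p.spec for p in pa}
    specs_b = {p.spec for p in pb}
    if specs_a != specs_b:
        raise ValueError(f"spec mismatch between sets: {specs_a} vs {specs_b}")

    rows = []
    for spec in sorted(specs_a):
        ic_a = np.array([i_critical(p) for p in pa if p.spec == spec])
        ic_b = np.array([i_critical(p) for p in pb if p.spec == spec])
        ic_a = ic_a[~np.isnan(ic_a)]
        ic_b = ic_b[~np.isnan(ic_b)]
        mean_a = float(np.mean(ic_a)) if len(ic_a) else math.nan
        mean_b = float(np.mean(ic_b)) if len(ic_b) else math.nan
        rows.append({
            "range": spec[0], "class": spec[1],
            "n_a": len(ic_a), "n_b": len(ic_b),
            "mean_a": mean_a, "mean_b": mean_b,
            "min_a": float(np.min(ic_a)) if len(ic_a) else math.nan,
            "max_a": float(np.max(ic_a)) if len(ic_a) else math.nan,
            "min_b": float(np.min(ic_b)) if len(ic_b) else math.nan,
            "max_b": float(np.max(ic_b)) if len(ic_b) else math.nan,
            "delta_mean": mean_a - mean_b,
        })
    return pd.DataFrame(rows)
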