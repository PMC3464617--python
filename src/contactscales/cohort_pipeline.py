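"""Batch analysis of a structure set and cohort-level aggregation.

``run_cohort`` validates every structure, computes (or accepts) the
normalization table, builds contact maps, and aggregates per-slice
component statistics (cluster size, assortativity, clustering), the
per-range degree/strength summaries, and the clique dominance
distributions.  The analysis path contains no randomness: rerunning on
the same inputs and configuration is bit-identical.

Because every downstream number depends on the normalization factors, the
provenance of the table in use is carried into each output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clique_analysis import CLIQUE_TYPES, census
from .contact_network import (
    DEFAULT_CUTOFF,
    NormalizationTable,
    build_contact_map,
    compute_normalization,
)
from .structure_io import Structure, validate_structure
from .subnetworks import NetworkSpec, build_graph
from .topology_metrics import graph_metrics, whole_graph_metrics

__all__ = [
    "DEFAULT_SLICES",
    "CohortConfig",
    "CohortSummary",
    "run_cohort",
    "composition_excess",
]

#: the (range, class) slices summarized by default
DEFAULT_SLICES = (
    ("lrn", "bn"), ("lrn", "in"), ("lrn", "an"),
    ("srn", "bn"), ("srn", "an"),
    ("arn", "bn"), ("arn", "in"), ("arn", "cn"), ("arn", "an"),
)


@dataclass(frozen=True)
class CohortConfig:
    cutoff: float = DEFAULT_CUTOFF
    i_min: float = 0.0
    min_component_size: int = 30
    slices: tuple[tuple[str, str], ...] = DEFAULT_SLICES
    norm_table: NormalizationTable | None = None
    sd_over: str = "components"  # or "proteins"

    def __post_init__(self) -> None:
        if self.sd_over not in ("components", "proteins"):
            raise ValueError("sd_over must be 'components' or 'proteins'")


@dataclass
class CohortSummary:
    """Aggregated cohort statistics.

    ``slice_table`` holds per-(range, class) means and standard deviations
    of component size, assortativity r and clustering C over components of
    at least the size threshold, plus the assortative fraction (% of
    qualifying components with r > 0).  ``components`` is the raw
    per-component table the aggregates derive from, suitable for external
    significance testing.
    """

    n_structures: int
    excluded: list[str]
    norm_provenance: str
    slice_table: pd.DataFrame
    components: pd.DataFrame
    range_summary: pd.DataFrame
    clique_dominance: pd.DataFrame
    perimeter_dominance: pd.DataFrame
    composition: pd.DataFrame

    @property
    def composition_excess(self) -> int:
        """Proteins with more hydrophilic than hydrophobic residues."""
        return int((self.composition["n_I"] > self.composition["n_B"]).sum())


def composition_excess(structures: Iterable[Structure]) -> int:
    """Count structures with strictly more hydrophilic than hydrophobic residues."""
    count = 0
    for s in structures:
        c = s.class_counts()
        if c["I"] > c["B"]:
            count += 1
    return count


def _distribution(per_protein: dict[str, str | None]) -> pd.DataFrame:
    """Relative frequency (%) of a per-protein categorical outcome."""
    rows = []
    values = [v for v in per_protein.values() if v is not None]
    for t in CLIQUE_TYPES:
        n = sum(1 for v in values if v == t)
        rows.append({"type": t, "count": n,
                     "percent": 100.0 * n / len(values) if values else math.nan})
    return pd.DataFrame(rows)


def run_cohort(structures: Sequence[Structure],
               config: CohortConfig | None = None) -> CohortSummary:
    """Run the full analysis battery over a structure set.

    Structures failing validation (a residue with no atoms) are excluded
    and reported in ``excluded``.  When no normalization table is given it
    is computed from the surviving set itself.
    """
    config = config or CohortConfig()
    if not structures:
        raise ValueError("empty structure set")

    kept: list[Structure] = []
    excluded: list[str] = []
    for s in structures:
        if validate_structure(s).rejectable:
            excluded.append(s.id)
        else:
            kept.append(s)
    if not kept:
        raise ValueError("no structure passed validation")

    table = config.norm_table or compute_normalization(kept, cutoff=config.cutoff)
    maps = [build_contact_map(s, table, cutoff=config.cutoff) for s in kept]

    comp_rows = []
    range_rows = []
    dominant: dict[str, dict[str, str | None]] = {r: {} for r in ("arn", "lrn", "srn")}
    max_perim: dict[str, dict[str, str | None]] = {r: {} for r in ("arn", "lrn")}
    comp_counts = []

    for s, cm in zip(kept, maps):
        cc = s.class_counts()
        comp_counts.append({"structure_id": s.id, "length": s.length,
                            "n_B": cc["B"], "n_I": cc["I"], "n_C": cc["C"]})

        for rng_f, cls_f in config.slices:
            g = build_graph(cm, NetworkSpec(rng_f, cls_f, config.i_min))
            cms = graph_metrics(g, min_component_size=config.min_component_size)
            for rank, m in enumerate(cms.per_component, start=1):
                comp_rows.append({
                    "structure_id": s.id, "range": rng_f, "class": cls_f,
                    "component_rank": rank, "n_nodes": m.n_nodes,
                    "n_edges": m.n_edges, "r": m.r,
                    "mean_clustering": m.mean_clustering,
                    "mean_degree": m.mean_degree,
                    "mean_edge_strength": m.mean_edge_strength,
                })

        for rng_f in ("arn", "lrn", "srn"):
            g = build_graph(cm, NetworkSpec(rng_f, "an", config.i_min))
            whole = whole_graph_metrics(g)
            range_rows.append({
                "structure_id": s.id, "range": rng_f,
                "mean_degree": whole.mean_degree,
                "mean_edge_strength": whole.mean_edge_strength,
                "n_edges": whole.n_edges,
            })
            cen = census(g, class_counts=cc)
            dominant[rng_f][s.id] = cen.dominant_type
            if rng_f in max_perim:
                max_perim[rng_f][s.id] = cen.max_perimeter_type

    components = pd.DataFrame(comp_rows)
    slice_rows = []
    for rng_f, cls_f in config.slices:
        if len(components):
            sub = components[(components["range"] == rng_f)
                             & (components["class"] == cls_f)]
        else:
            sub = components
        if config.sd_over == "proteins" and len(sub):
            sub = sub.groupby("structure_id", as_index=False).mean(numeric_only=True)
        r_vals = sub["r"].dropna() if len(sub) else pd.Series(dtype=float)
        slice_rows.append({
            "range": rng_f, "class": cls_f,
            "n_components": len(sub),
            "mean_size": float(sub["n_nodes"].mean()) if len(sub) else math.nan,
            "sd_size": float(sub["n_nodes"].std(ddof=0)) if len(sub) else math.nan,
            "mean_r": float(r_vals.mean()) if len(r_vals) else math.nan,
            "sd_r": float(r_vals.std(ddof=0)) if len(r_vals) else math.nan,
            "mean_clustering": float(sub["mean_clustering"].mean()) if len(sub) else math.nan,
            "sd_clustering": float(sub["mean_clustering"].std(ddof=0)) if len(sub) else math.nan,
            "assortative_fraction": (
                100.0 * float((sub["r"] > 0).sum()) / len(sub) if len(sub) else math.nan
            ),
        })

    range_df = pd.DataFrame(range_rows)
    range_summary = (
        range_df.groupby("range", as_index=False)
        .agg(mean_degree=("mean_degree", "mean"),
             mean_edge_strength=("mean_edge_strength", "mean"),
             mean_edges=("n_edges", "mean"))
    )

    return CohortSummary(
        n_structures=len(kept),
        excluded=excluded,
        norm_provenance=table.provenance,
        slice_table=pd.DataFrame(slice_rows),
        components=components,
        range_summary=range_summary,
        clique_dominance=pd.concat(
            [_distribution(dominant[r]).assign(range=r) for r in ("arn", "lrn", "srn")],
            ignore_index=True,
        ),
        perimeter_dominance=pd.concat(
            [_distribution(max_perim[r]).assign(range=r) for r in ("arn", "lrn")],
            ignore_index=True,
        ),
        composition=pd.DataFrame(comp_counts),
    )
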