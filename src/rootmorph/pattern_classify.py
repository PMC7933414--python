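"""Classification of a final activator field into root-pattern types.

The simulated fields are effectively two-phase (the saturation clamp pushes
cells toward activator-high or activator-low levels).  Cells are binarised
at the mid-range threshold, the minority phase (by total cell area) defines
the "spots", and its connected components over the cell adjacency graph are
the candidate root regions:

* polarity is ``spotted`` when the minority phase is the HIGH phase (spots
  of concentrated activator) and ``reverse_spotted`` when it is LOW;
* 1-4 compact regions are read as 1-4 roots;
* a single elongated region wrapping far around the tissue centre is read
  as a C-shaped root;
* anything else (homogeneous field, >4 regions, non-compact multi-region
  fields) is ``other``.

Compactness uses circularity 4*pi*A/P^2 (1 for a disk); the C-shape rule
(circularity < 0.4 and angular extent >= 120 degrees around the tissue
centroid) is an explicit operationalisation of a judgement the source data
for this model made visually, with thresholds fixed here in code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import CellNetwork
from .reaction_diffusion import RDState

__all__ = ["RegionMetrics", "PatternSummary", "binarize", "regions",
           "classify", "CIRCULARITY_COMPACT", "C_SHAPE_MIN_ANGLE_DEG"]

HOMOGENEITY_FRACTION = 0.05   # of u0: below this range the field is flat
CIRCULARITY_COMPACT = 0.4
C_SHAPE_MIN_ANGLE_DEG = 120.0


@dataclass(frozen=True)
class RegionMetrics:
    cell_ids: tuple[int, ...]
    area_fraction: float
    circularity: float
    centroid: tuple[float, float]
    angular_extent_deg: float


@dataclass(frozen=True)
class PatternSummary:
    polarity: str            # "spotted" | "reverse_spotted" | "none"
    n_regions: int
    root_label: str          # "1".."4" | "C" | "other"
    regions: tuple[RegionMetrics, ...]


def binarize(state: RDState, network: CellNetwork, u_0: float) -> np.ndarray | None:
    """Boolean HIGH labels per cell (aligned to ``state.cell_ids``) at the
    mid-range threshold; ``None`` when the field is homogeneous (u range
    below 5% of the equilibrium u_0).

    The mid-range threshold makes labels invariant under affine rescaling
    of u, which keeps the classification stable across saturation regimes.
    """
    u = state.u
    if u.size == 0:
        raise ValueError("empty state")
    lo, hi = float(u.min()), float(u.max())
    if hi - lo < HOMOGENEITY_FRACTION * u_0:
        return None
    return u > 0.5 * (lo + hi)


def regions(network: CellNetwork, labels: np.ndarray,
            cell_ids: np.ndarray) -> tuple[list[list[int]], str]:
    """Connected components of the minority phase and the polarity.

    The minority phase is whichever label occupies < 50% of the total cell
    area; an exact tie is broken toward HIGH as the minority.  Components
    are taken over the wall-sharing adjacency graph.
    """
    areas = np.array([network.cell_area(int(c)) for c in cell_ids])
    high_area = float(areas[labels].sum())
    minority_high = high_area <= 0.5 * float(areas.sum())
    polarity = "spotted" if minority_high else "reverse_spotted"
    in_phase = labels if minority_high else ~labels
    phase_cells = {int(c) for c, m in zip(cell_ids, in_phase) if m}
    g = nx.Graph()
    g.add_nodes_from(phase_cells)
    g.add_edges_from((a, b) for a, b in network.adjacency_edges()
                     if a in phase_cells and b in phase_cells)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    return comps, polarity


def _region_metrics(network: CellNetwork, comp: list[int],
                    total_area: float, net_centroid: np.ndarray) -> RegionMetrics:
    cells = set(comp)
    area = sum(network.cell_area(c) for c in comp)
    perim = 0.0
    for w in network.walls.values():
        # boundary of the region: interface walls and outer-boundary walls
        # of region cells both have exactly one adjacent cell in the region
        inside = sum(1 for c in w.cells if c in cells)
        if inside == 1:
            perim += network.wall_length(w.id)
    circ = 4 * math.pi * area / perim**2 if perim > 0 else 1.0
    centroid = np.zeros(2)
    angles = []
    for c in comp:
        cc = network.cell_centroid(c)
        centroid += network.cell_area(c) * cc
        d = cc - net_centroid
        angles.append(math.atan2(d[1], d[0]))
    centroid /= area
    ext = _angular_span_deg(angles)
    return RegionMetrics(tuple(comp), area / total_area, circ,
                         (float(centroid[0]), float(centroid[1])), ext)


def _angular_span_deg(angles: list[float]) -> float:
    """Smallest arc (degrees) containing all angles: 360 minus the largest
    gap between consecutive sorted angles."""
    if len(angles) == 1:
        return 0.0
    a = np.sort(np.asarray(angles))
    gaps = np.diff(a)
    wrap = 2 * math.pi - (a[-1] - a[0])
    return math.degrees(2 * math.pi - max(gaps.max(), wrap))


def classify(network: CellNetwork, state: RDState, u_0: float) -> PatternSummary:
    """Full pattern readout: polarity, region count and root-type label."""
    labels = binarize(state, network, u_0)
    if labels is None:
        return PatternSummary("none", 0, "other", ())
    comps, polarity = regions(network, labels, state.cell_ids)
    total_area = sum(network.cell_area(c) for c in network.cell_ids())
    net_c = network.network_centroid()
    metrics = tuple(_region_metrics(network, c, total_area, net_c)
                    for c in comps)
    n = len(comps)
    label = "other"
    if 1 <= n <= 4 and all(m.circularity >= CIRCULARITY_COMPACT
                           for m in metrics):
        label = str(n)
    elif n == 1 and metrics[0].circularity < CIRCULARITY_COMPACT \
            and metrics[0].angular_extent_deg >= C_SHAPE_MIN_ANGLE_DEG:
        label = "C"
    return PatternSummary(polarity, n, label, metrics)
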