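"""Voronoi density-based cluster segmentation and inter-channel distances.

Clusters are segmented by thresholding the first-rank density at a
multiple of a reference density (strict ``>``) and grouping the
selected localizations into connected components of the Delaunay
adjacency.  Two levels are supported: level-1 "contour" objects are
segmented against the whole-image average density; level-2
"nanoclusters" are re-segmented inside each contour against that
contour's own average density.  The distance between channels is the
Euclidean distance between cluster barycenters (each cluster of one
channel to its nearest in the other).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .tessellation import VoronoiTessellation


@dataclasses.dataclass
class Cluster:
    """A connected group of above-threshold localizations."""

    member_indices: np.ndarray
    barycenter: np.ndarray
    level: str = "contour"  # or "nanocluster"

    @property
    def n_members(self) -> int:
        return self.member_indices.size


def _mean_member_density(model: VoronoiTessellation, members: np.ndarray) -> float:
    """Average localization density over a subset of seeds' cells.

    Computed as the mean first-rank density of the member seeds (edge-
    flagged seeds excluded)."""
    d = model.density[members]
    d = d[d > 0]
    return float(d.mean()) if d.size else 0.0


def segment(
    model: VoronoiTessellation,
    threshold_multiplier: float = 2.0,
    within: Optional[Cluster] = None,
    min_size: int = 5,
    level: Optional[str] = None,
) -> list[Cluster]:
    """Segment clusters by density thresholding + Delaunay connectivity.

    Seeds with ``delta_i > threshold_multiplier x reference`` are
    selected; the reference is the whole-image average density
    (``model.delta_ref``), or, when ``within`` is given, the average
    density over that cluster's members.  Selected seeds are grouped
    into connected components of the Delaunay adjacency restricted to
    the selection; components smaller than ``min_size`` are discarded.
    """
    if within is None:
        reference = model.delta_ref
        domain = np.arange(model.n)
        level = level or "contour"
    else:
        reference = _mean_member_density(model, within.member_indices)
        domain = within.member_indices
        level = level or "nanocluster"

    in_domain = np.zeros(model.n, dtype=bool)
    in_domain[domain] = True
    selected = in_domain & (model.density > threshold_multiplier * reference)
    boundary = getattr(model, "boundary_flag", None)
    if boundary is not None:
        # guard zone: first-rank densities pooling window-edge cells carry
        # reflection-amplified fluctuations and cannot seed clusters
        counts = np.diff(model.neighbor_indptr)
        contaminated = boundary.copy()
        np.add.at(
            contaminated,
            model.neighbor_indices[np.repeat(boundary, counts)],
            True,
        )
        selected &= ~contaminated
    sel_idx = np.flatnonzero(selected)
    if sel_idx.size == 0:
        return []

    # adjacency among selected seeds only
    local = -np.ones(model.n, dtype=np.intp)
    local[sel_idx] = np.arange(sel_idx.size)
    rows, cols = [], []
    counts = np.diff(model.neighbor_indptr)
    src = np.repeat(np.arange(model.n), counts)
    dst = model.neighbor_indices
    edge_ok = selected[src] & selected[dst]
    rows = local[src[edge_ok]]
    cols = local[dst[edge_ok]]
    graph = csr_matrix(
        (np.ones(rows.size, dtype=np.int8), (rows, cols)),
        shape=(sel_idx.size, sel_idx.size),
    )
    n_comp, comp = connected_components(graph, directed=False)

    clusters = []
    for c in range(n_comp):
        members = sel_idx[comp == c]
        if members.size < min_size:
            continue
        barycenter = model.seeds.coords[members].mean(axis=0)
        clusters.append(Cluster(members, barycenter, level))
    return clusters


def segment_two_level(
    model: VoronoiTessellation,
    threshold_multiplier: float = 2.0,
    min_size: int = 5,
) -> tuple[list[Cluster], list[Cluster]]:
    """Level-1 contours against the image density, then nanoclusters
    within each contour against the contour's own average density."""
    contours = segment(model, threshold_multiplier, min_size=min_size)
    nanoclusters = []
    for contour in contours:
        nanoclusters.extend(
            segment(model, threshold_multiplier, within=contour, min_size=min_size)
        )
    return contours, nanoclusters


def cluster_distance(
    clusters_A: Sequence[Cluster], clusters_B: Sequence[Cluster]
) -> np.ndarray:
    """Per-A-cluster distance to the nearest B-cluster barycenter (nm).

    Returns NaN for every entry when the B list is empty.
    """
    if len(clusters_A) == 0:
        return np.empty(0)
    if len(clusters_B) == 0:
        return np.full(len(clusters_A), np.nan)
    bary_A = np.array([c.barycenter for c in clusters_A])
    bary_B = np.array([c.barycenter for c in clusters_B])
    return cdist(bary_A, bary_B).min(axis=1)
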