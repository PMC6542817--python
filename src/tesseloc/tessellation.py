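"""Per-channel Voronoi tessellation and first-rank density estimation.

Every localization :math:`s_i` owns one Voronoi polytope :math:`P_i`
(polygon in 2D, polyhedron in 3D).  Its first-rank density pools the
cell with its facet-sharing neighbors,

.. math::

    \\delta_i = \\frac{n_i + 1}{A_i + \\sum_{j \\in N(i)} A_j},

where :math:`n_i` is the neighbor count and :math:`A_i` the cell area
(volume in 3D).  Densities are normalized by the average density
:math:`\\delta` of a spatially random reference over the region of
interest, :math:`\\hat\\delta_i = \\delta_i / \\delta`, which makes the
descriptor independent of the absolute molecular density.

Boundary treatment: seeds near the ROI faces are mirrored across them
before tessellating, so border cells are finite and clipped exactly at
the ROI — the standard reflection edge correction for window-limited
density estimation.  Any seed whose own cell, or any first-rank
neighbor cell, still ends up unbounded cannot be assigned a meaningful
density and gets :math:`\\hat\\delta_i = 0` (it falls into the
background class downstream).
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, Voronoi, cKDTree
from scipy.spatial import QhullError

from .errors import ConfigError, GeometryError
from .io import LocalizationSet


@dataclasses.dataclass
class VoronoiTessellation:
    """Voronoi diagram of one channel with per-seed density descriptors.

    Attributes
    ----------
    seeds
        The localizations the diagram was built from.
    cell_measure
        Per-seed cell area (nm^2) or volume (nm^3); ``+inf`` for
        unbounded cells.
    neighbor_indptr, neighbor_indices
        First-rank adjacency (cells sharing an edge/facet) in CSR form:
        the neighbors of seed ``i`` are
        ``neighbor_indices[neighbor_indptr[i]:neighbor_indptr[i+1]]``.
    density
        First-rank density ``delta_i`` (nm^-dim); 0 for edge-flagged
        seeds.
    edge_flag
        True where the seed's own or any neighbor cell is unbounded.
    delta_ref
        Reference density ``delta`` = n / measure(roi).
    delta_hat
        Normalized density ``density / delta_ref`` (dimensionless).
    roi
        Axis-aligned reference box as ``(lo, hi)`` arrays.
    """

    seeds: LocalizationSet
    cell_measure: np.ndarray
    neighbor_indptr: np.ndarray
    neighbor_indices: np.ndarray
    density: np.ndarray
    edge_flag: np.ndarray
    delta_ref: float
    delta_hat: np.ndarray
    roi: tuple[np.ndarray, np.ndarray]
    boundary_flag: np.ndarray = dataclasses.field(default=None)
    _kdtree: Optional[cKDTree] = dataclasses.field(default=None, repr=False)
    _delaunay: Optional[Delaunay] = dataclasses.field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.seeds.n

    @property
    def dim(self) -> int:
        return self.seeds.dim

    def neighbors_of(self, i: int) -> np.ndarray:
        return self.neighbor_indices[self.neighbor_indptr[i] : self.neighbor_indptr[i + 1]]

    @property
    def kdtree(self) -> cKDTree:
        if self._kdtree is None:
            self._kdtree = cKDTree(self.seeds.coords)
        return self._kdtree

    @property
    def delaunay(self) -> Delaunay:
        """Delaunay triangulation dual to the diagram (lazily built)."""
        if self._delaunay is None:
            self._delaunay = Delaunay(self.seeds.coords)
        return self._delaunay

    def locate(self, queries: np.ndarray) -> np.ndarray:
        """Index of the cell containing each query point.

        Equivalent to the nearest seed under Euclidean distance; exact
        distance ties are broken toward the lowest seed index.
        """
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        if queries.shape[1] != self.dim:
            raise ConfigError(
                f"query dim {queries.shape[1]} != tessellation dim {self.dim}"
            )
        k = min(4, self.n)
        dist, idx = self.kdtree.query(queries, k=k)
        if k == 1:
            return np.atleast_1d(idx)
        # among neighbors at exactly the minimal distance, take min index
        tied = dist == dist[:, [0]]
        masked = np.where(tied, idx, self.n)
        return masked.min(axis=1)


def _polygon_areas_2d(vor: Voronoi) -> np.ndarray:
    """Areas of all Voronoi cells (inf for unbounded), vectorized shoelace."""
    n = vor.points.shape[0]
    regions = [vor.regions[r] for r in vor.point_region]
    lengths = np.fromiter((len(r) for r in regions), dtype=np.intp, count=n)
    flat = np.fromiter(itertools.chain.from_iterable(regions), dtype=np.intp)
    starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    unbounded_mask = np.zeros(n, dtype=bool)
    open_region = flat == -1
    if open_region.any():
        owner = np.repeat(np.arange(n), lengths)
        unbounded_mask[np.unique(owner[open_region])] = True
    unbounded_mask |= lengths < 3

    verts = vor.vertices[np.where(flat < 0, 0, flat)]
    # next vertex within each polygon (wrap-around)
    nxt = np.arange(flat.size) + 1
    ends = starts + lengths - 1
    nxt[ends[lengths > 0]] = starts[lengths > 0]
    cross = verts[:, 0] * verts[nxt, 1] - verts[nxt, 0] * verts[:, 1]
    areas = 0.5 * np.abs(np.add.reduceat(cross, starts))
    areas[lengths == 0] = 0.0
    areas[unbounded_mask] = np.inf
    return areas


def _polyhedron_volumes_3d(vor: Voronoi) -> np.ndarray:
    """Volumes of all 3D Voronoi cells (inf for unbounded)."""
    n = vor.points.shape[0]
    volumes = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if len(region) < 4 or -1 in region:
            volumes[i] = np.inf
            continue
        try:
            volumes[i] = ConvexHull(vor.vertices[region]).volume
        except QhullError:
            volumes[i] = np.inf
    return volumes


def _adjacency_csr(ridge_points: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric CSR adjacency from Voronoi ridge (facet) pairs."""
    if ridge_points.size == 0:
        return np.zeros(n + 1, dtype=np.intp), np.empty(0, dtype=np.intp)
    a = ridge_points[:, 0]
    b = ridge_points[:, 1]
    src = np.concatenate([a, b])
    dst = np.concatenate([b, a])
    order = np.argsort(src, kind="stable")
    src, dst = src[order], dst[order]
    counts = np.bincount(src, minlength=n)
    indptr = np.concatenate(([0], np.cumsum(counts)))
    return indptr.astype(np.intp), dst.astype(np.intp)


def _mirror_pad(pts: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                width: float) -> np.ndarray:
    """Reflections of near-boundary points across each ROI face.

    Padding the seed set this way bounds the border cells and clips
    them exactly at the ROI faces (the bisector between a point and its
    reflection is the face itself), the usual edge correction for
    density estimation on a finite window.
    """
    pads = []
    eps = 1e-9 * float(np.max(hi - lo))
    for ax in range(pts.shape[1]):
        for face, sign in ((lo[ax], -1.0), (hi[ax], 1.0)):
            band = pts[np.abs(pts[:, ax] - face) <= width]
            if band.size:
                mirrored = band.copy()
                mirrored[:, ax] = 2 * face - mirrored[:, ax]
                # seeds exactly on the face would mirror onto themselves;
                # nudge their images just outside so the face still cuts
                on_face = np.abs(band[:, ax] - face) < eps
                mirrored[on_face, ax] = face + sign * eps
                pads.append(mirrored)
    return np.concatenate(pads) if pads else np.empty((0, pts.shape[1]))


def reference_density(locs: LocalizationSet, roi) -> float:
    """Average density of a spatially random reference: n / measure(roi)."""
    lo, hi = (np.asarray(b, dtype=float) for b in roi)
    measure = float(np.prod(hi - lo))
    if measure <= 0:
        raise ConfigError("ROI must have positive measure")
    if locs.n == 0:
        raise ValueError("cannot compute a reference density for an empty channel")
    return locs.n / measure


def build_tessellation(
    locs: LocalizationSet, roi=None, pad: bool = True
) -> VoronoiTessellation:
    """Build the Voronoi diagram of one channel and its density field.

    Parameters
    ----------
    locs
        Channel localizations; at least ``dim + 2`` non-degenerate seeds.
    roi
        Optional ``(lo, hi)`` axis-aligned box used for the reference
        density; defaults to the seeds' bounding box.
    pad
        Mirror near-boundary seeds across the ROI faces before
        tessellating, which bounds the border cells and clips them at
        the ROI exactly.  With ``pad=False`` border cells stay unbounded
        and are handled by the edge flag / zero-density rule alone.

    Raises
    ------
    GeometryError
        For too few or degenerate (collinear/coplanar) seeds.
    """
    pts = locs.coords
    n = locs.n
    if n < locs.dim + 2:
        raise GeometryError(
            f"need at least {locs.dim + 2} seeds in {locs.dim}D, got {n}"
        )
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(pts).max())) < locs.dim:
        raise GeometryError(
            "degenerate seed configuration (collinear/coplanar points)"
        )
    if roi is None:
        roi = (pts.min(axis=0), pts.max(axis=0))
    lo, hi = (np.asarray(b, dtype=float) for b in roi)
    delta_ref = reference_density(locs, (lo, hi))

    all_pts = pts
    if pad:
        # band wide enough to cover several cell diameters
        spacing = (float(np.prod(hi - lo)) / n) ** (1.0 / locs.dim)
        mirrored = _mirror_pad(pts, lo, hi, width=5.0 * spacing)
        if mirrored.shape[0]:
            all_pts = np.concatenate([pts, mirrored])
    n_all = all_pts.shape[0]

    try:
        vor = Voronoi(all_pts)
    except QhullError as exc:
        raise GeometryError(f"degenerate seed configuration: {exc}") from exc

    if locs.dim == 2:
        measures_all = _polygon_areas_2d(vor)
    else:
        measures_all = _polyhedron_volumes_3d(vor)

    indptr, indices = _adjacency_csr(vor.ridge_points, n_all)
    n_neighbors = np.diff(indptr)

    unbounded = ~np.isfinite(measures_all)
    # a seed is edge-flagged if its own cell or any neighbor cell
    # (mirrored ones included) is unbounded
    edge_flag_all = unbounded.copy()
    touches = np.zeros(n_all, dtype=bool)
    np.add.at(touches, indices[np.repeat(unbounded, n_neighbors)], True)
    edge_flag_all |= touches

    finite_measures = np.where(unbounded, 0.0, measures_all)
    owner = np.repeat(np.arange(n_all), n_neighbors)
    neighbor_sum = np.bincount(
        owner, weights=finite_measures[indices], minlength=n_all
    )
    # isolated seeds (no ridge survived qhull merging) are unusable
    edge_flag_all |= n_neighbors == 0

    density_all = np.zeros(n_all)
    ok = ~edge_flag_all
    density_all[ok] = (n_neighbors[ok] + 1) / (
        finite_measures[ok] + neighbor_sum[ok]
    )

    # cells sharing a facet with a mirrored cell touch the ROI boundary
    boundary_flag = edge_flag_all[:n].copy()
    if n_all > n:
        mixed = vor.ridge_points[(vor.ridge_points < n).any(axis=1)
                                 & (vor.ridge_points >= n).any(axis=1)]
        boundary_flag[np.unique(mixed[mixed < n])] = True
        # public adjacency: real-seed edges only (mirrored seeds are an
        # internal boundary construction)
        real_edges = vor.ridge_points[(vor.ridge_points < n).all(axis=1)]
        indptr, indices = _adjacency_csr(real_edges, n)

    density = density_all[:n]
    delta_hat = density / delta_ref

    return VoronoiTessellation(
        seeds=locs,
        cell_measure=measures_all[:n],
        neighbor_indptr=indptr[: n + 1],
        neighbor_indices=indices,
        density=density,
        edge_flag=edge_flag_all[:n],
        delta_ref=delta_ref,
        delta_hat=delta_hat,
        roi=(lo, hi),
        boundary_flag=boundary_flag,
    )


def first_rank_density(model: VoronoiTessellation) -> np.ndarray:
    """Per-seed first-rank density ``delta_i`` (0 for edge-flagged seeds)."""
    return model.density
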