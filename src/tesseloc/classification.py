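"""Five-class density classification and Delaunay edge-effect correction.

With both channels tessellated, every localization of channel A is
paired to the channel-B cell it falls into (and vice versa), giving a
pair-density descriptor ``(delta_hat_own, delta_hat_partner)``.  A
single threshold ``T`` on the normalized density splits each channel
into a high-density class and background; the partner density then
splits each high class into colocalized (AB, BA) and non-colocalized
(Ab, Ba) subclasses:

- ``AB``: high in A and inside a high-density cell of B,
- ``Ab``: high in A, partner density below T,
- ``BA``/``Ba``: the mirrored classes of channel B,
- ``bg``: below threshold in its own channel.

Voronoi cells on the rim of a dense structure are systematically larger
than interior cells, which can spuriously promote rim localizations to
AB/BA.  The correction re-tests each AB (resp. BA) localization against
the Delaunay triangle set of the other channel's high class: triangles
whose measure exceeds ``q75 + 1.5 * IQR`` are discarded as outliers, and
a localization keeps its colocalized label only if it lies inside a kept
simplex (boundary inclusive); otherwise it is demoted to Ab (resp. Ba).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy.spatial import Delaunay

from .errors import ConfigError
from .tessellation import VoronoiTessellation

#: class labels used throughout (lowercase letter = "not high in that channel")
LABELS = ("AB", "Ab", "BA", "Ba", "bg")


@dataclasses.dataclass
class PairDescriptorTable:
    """Scatterplot coordinates for both channels.

    For channel A, row ``i`` is ``(x_A[i], y_A[i]) =
    (delta_hat_A[i], delta_hat_B[partner_A[i]])`` where ``partner_A[i]``
    is the channel-B cell containing localization ``i`` of A.  Channel B
    rows keep the same axis convention (A on x, B on y):
    ``(x_B[i], y_B[i]) = (delta_hat_A[partner_B[i]], delta_hat_B[i])``.
    """

    x_A: np.ndarray
    y_A: np.ndarray
    partner_A: np.ndarray
    x_B: np.ndarray
    y_B: np.ndarray
    partner_B: np.ndarray

    @property
    def n_A(self) -> int:
        return self.x_A.size

    @property
    def n_B(self) -> int:
        return self.y_B.size

    def swapped(self) -> "PairDescriptorTable":
        """The same table with the channel roles exchanged."""
        return PairDescriptorTable(
            x_A=self.y_B,
            y_A=self.x_B,
            partner_A=self.partner_B,
            x_B=self.y_A,
            y_B=self.x_A,
            partner_B=self.partner_A,
        )


def pair_densities(
    model_A: VoronoiTessellation, model_B: VoronoiTessellation
) -> PairDescriptorTable:
    """Pair every localization with the other channel's containing cell."""
    if model_A.dim != model_B.dim:
        raise ConfigError("channels have different dimensionality")
    partner_A = model_B.locate(model_A.seeds.coords)
    partner_B = model_A.locate(model_B.seeds.coords)
    return PairDescriptorTable(
        x_A=model_A.delta_hat,
        y_A=model_B.delta_hat[partner_A],
        partner_A=partner_A,
        x_B=model_A.delta_hat[partner_B],
        y_B=model_B.delta_hat,
        partner_B=partner_B,
    )


@dataclasses.dataclass
class TriangleSet:
    """Delaunay simplices of one channel restricted to its high class.

    A simplex belongs to the set when all ``dim + 1`` vertices are in
    the high-density class.  Simplices with measure above
    ``q75 + 1.5 * IQR`` of the member measure distribution (quartiles by
    linear interpolation) are marked as outliers and excluded from
    point-membership tests.
    """

    delaunay: Optional[Delaunay]
    simplex_indices: np.ndarray  # indices into delaunay.simplices
    measures: np.ndarray
    kept: np.ndarray  # bool per member simplex
    q25: float
    q75: float

    @property
    def iqr(self) -> float:
        return self.q75 - self.q25

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership of each point in any kept simplex."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.delaunay is None or self.n_kept == 0:
            return np.zeros(points.shape[0], dtype=bool)
        tri = self.delaunay
        kept_lookup = np.zeros(tri.simplices.shape[0], dtype=bool)
        kept_lookup[self.simplex_indices[self.kept]] = True

        found = tri.find_simplex(points)
        result = np.zeros(points.shape[0], dtype=bool)
        inside = found >= 0
        result[inside] = kept_lookup[found[inside]]

        # Points located in a non-kept simplex may still sit exactly on a
        # facet shared with a kept one; re-test those few by scanning the
        # kept simplices directly so the result matches an exhaustive scan.
        candidates = np.flatnonzero(inside & ~result)
        if candidates.size:
            bary = self._barycentric(points[candidates], found[candidates])
            on_facet = candidates[bary.min(axis=1) <= 1e-9]
            for idx in on_facet:
                result[idx] = self._scan_kept(points[idx])
        return result

    def _barycentric(self, pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
        T = self.delaunay.transform[simplices]
        b = np.einsum("ijk,ik->ij", T[:, :-1, :], pts - T[:, -1, :])
        return np.column_stack([b, 1.0 - b.sum(axis=1)])

    def _scan_kept(self, point: np.ndarray) -> bool:
        members = self.simplex_indices[self.kept]
        bary = self._barycentric(
            np.broadcast_to(point, (members.size, point.size)), members
        )
        return bool(np.any(bary.min(axis=1) >= -1e-9))


def _simplex_measures(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Areas (2D) or volumes (3D) of triangulation simplices."""
    dim = points.shape[1]
    verts = points[simplices]
    edges = verts[:, 1:, :] - verts[:, :1, :]
    if dim == 2:
        det = edges[:, 0, 0] * edges[:, 1, 1] - edges[:, 0, 1] * edges[:, 1, 0]
        return np.abs(det) / 2.0
    det = np.linalg.det(edges)
    return np.abs(det) / 6.0


def build_triangle_set(delaunay: Delaunay, high_mask: np.ndarray) -> TriangleSet:
    """Collect the high-class simplices of one channel and prune outliers.

    The quartiles are taken over the measure distribution of the whole
    triangulation, so the cutoff reflects the channel's overall triangle
    scale; only clearly oversized member simplices (typically those
    spanning between separate dense structures or reaching into the
    background) are discarded, while the natural in-cluster area spread
    stays intact.
    """
    high_mask = np.asarray(high_mask, dtype=bool)
    member = high_mask[delaunay.simplices].all(axis=1)
    idx = np.flatnonzero(member)
    if idx.size == 0:
        return TriangleSet(delaunay, idx, np.empty(0), np.empty(0, dtype=bool),
                           float("nan"), float("nan"))
    all_measures = _simplex_measures(delaunay.points, delaunay.simplices)
    measures = all_measures[idx]
    q25, q75 = np.percentile(all_measures, [25, 75])  # linear interpolation
    cutoff = q75 + 1.5 * (q75 - q25)
    kept = measures <= cutoff
    return TriangleSet(delaunay, idx, measures, kept, float(q25), float(q75))


@dataclasses.dataclass
class ClassificationResult:
    """Per-localization five-class labels, before and after edge correction.

    ``labels_A`` / ``labels_B`` hold the final labels (strings from
    :data:`LABELS`); the ``pre_*`` arrays hold the labels before the
    Delaunay correction (identical when the correction is off).
    """

    labels_A: np.ndarray
    labels_B: np.ndarray
    pre_labels_A: np.ndarray
    pre_labels_B: np.ndarray
    T: float
    edge_correction: bool
    pairs: PairDescriptorTable

    # convenience views used by the writers
    @property
    def x_A(self) -> np.ndarray:
        return self.pairs.x_A

    @property
    def y_A(self) -> np.ndarray:
        return self.pairs.y_A

    @property
    def x_B(self) -> np.ndarray:
        return self.pairs.x_B

    @property
    def y_B(self) -> np.ndarray:
        return self.pairs.y_B

    def class_counts(self) -> dict:
        counts = {}
        for name in LABELS:
            counts[name] = int(
                (self.labels_A == name).sum() + (self.labels_B == name).sum()
            )
        return counts

    def high_mask_A(self) -> np.ndarray:
        """Pre-correction high-density membership of channel A."""
        return self.pairs.x_A >= self.T

    def high_mask_B(self) -> np.ndarray:
        return self.pairs.y_B >= self.T


def _three_way(own: np.ndarray, partner: np.ndarray, T: float,
               hi_lab: str, lone_lab: str) -> np.ndarray:
    labels = np.full(own.shape, "bg", dtype="U2")
    high = own >= T
    labels[high & (partner >= T)] = hi_lab
    labels[high & (partner < T)] = lone_lab
    return labels


def classify(
    pairs: PairDescriptorTable,
    T: float = 1.0,
    edge_correction: bool = True,
    model_A: Optional[VoronoiTessellation] = None,
    model_B: Optional[VoronoiTessellation] = None,
) -> ClassificationResult:
    """Classify both channels' localizations into the five classes.

    Thresholds are inclusive: ``delta_hat >= T`` is high, ``< T`` low.
    With ``edge_correction``, AB/BA labels are kept only for
    localizations falling inside the pruned Delaunay triangle set of the
    other channel's high class (requires ``model_A`` and ``model_B``).
    """
    if T < 0:
        raise ConfigError("threshold T must be non-negative")
    pre_A = _three_way(pairs.x_A, pairs.y_A, T, "AB", "Ab")
    pre_B = _three_way(pairs.y_B, pairs.x_B, T, "BA", "Ba")
    labels_A = pre_A.copy()
    labels_B = pre_B.copy()

    if edge_correction:
        if model_A is None or model_B is None:
            raise ConfigError("edge correction requires both tessellation models")
        tri_A = build_triangle_set(model_A.delaunay, pairs.x_A >= T)
        tri_B = build_triangle_set(model_B.delaunay, pairs.y_B >= T)
        labels_A, labels_B = edge_correct(
            pre_A, pre_B, tri_A, tri_B,
            model_A.seeds.coords, model_B.seeds.coords,
        )

    return ClassificationResult(
        labels_A=labels_A,
        labels_B=labels_B,
        pre_labels_A=pre_A,
        pre_labels_B=pre_B,
        T=T,
        edge_correction=edge_correction,
        pairs=pairs,
    )


def edge_correct(
    pre_A: np.ndarray,
    pre_B: np.ndarray,
    tri_A: TriangleSet,
    tri_B: TriangleSet,
    coords_A: np.ndarray,
    coords_B: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Demote AB/BA localizations outside the other channel's triangle set.

    Only AB -> Ab and BA -> Ba transfers happen; background and the
    lone-high classes are never touched.
    """
    labels_A = pre_A.copy()
    labels_B = pre_B.copy()
    ab = np.flatnonzero(pre_A == "AB")
    if ab.size:
        keep = tri_B.contains(coords_A[ab])
        labels_A[ab[~keep]] = "Ab"
    ba = np.flatnonzero(pre_B == "BA")
    if ba.size:
        keep = tri_A.contains(coords_B[ba])
        labels_B[ba[~keep]] = "Ba"
    return labels_A, labels_B
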