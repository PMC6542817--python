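"""Two-color registration and fiducial bead removal.

Chromatic aberration displaces channel B relative to channel A by a
field-dependent offset.  Two correction models are supported: a global
translation (the displacement between the fiducial barycenters of the
two channels) and a bi-dimensional third-order polynomial field
correction fitted on >= 10 paired fiducial markers.  Fiducial beads
themselves are removed from analysis data by a neighbor-count rule:
a bead emits in essentially every acquisition frame, so any
localization with at least ``frame_fraction x n_frames`` neighbors
within ``radius`` is discarded.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError, RegistrationError
from .io import LocalizationSet

#: exponents of the full bivariate cubic basis (a + b <= 3), 10 terms
_POLY3_POWERS = [(a, b) for total in range(4) for a in range(total + 1)
                 for b in [total - a]]


@dataclasses.dataclass
class RegistrationModel:
    """Mapping of channel-B coordinates into channel-A space.

    ``mode`` is ``"translation"`` (lateral displacement vector, plus an
    axial shift in 3D) or ``"poly3"`` (full bivariate cubic per lateral
    output coordinate, fitted by least squares).
    """

    mode: str
    translation: np.ndarray
    poly_coeffs: Optional[np.ndarray]  # (2, 10) for poly3, None otherwise
    fit_residual: float  # RMS pairing residual after correction, nm
    n_fiducials: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        out = coords.copy()
        if self.mode == "translation":
            out[:, : self.translation.size] += self.translation
            return out
        design = _poly3_design(coords[:, 0], coords[:, 1])
        out[:, 0] = design @ self.poly_coeffs[0]
        out[:, 1] = design @ self.poly_coeffs[1]
        if coords.shape[1] == 3:
            out[:, 2] = coords[:, 2] + self.translation[-1]
        return out


def _poly3_design(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack([x**a * y**b for a, b in _POLY3_POWERS])


def _mutual_nearest_pairs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Indices (i, j) of mutual nearest neighbors between two point sets."""
    ab = cKDTree(b).query(a)[1]
    ba = cKDTree(a).query(b)[1]
    i = np.arange(a.shape[0])
    mutual = ba[ab] == i
    return np.column_stack([i[mutual], ab[mutual]])


def fit_registration(
    fiducials_A: LocalizationSet,
    fiducials_B: LocalizationSet,
    mode: str = "translation",
) -> RegistrationModel:
    """Fit a chromatic correction from fiducial markers.

    Translation mode uses the barycenter displacement of the two
    fiducial clouds; poly3 mode pairs the fiducials by mutual nearest
    neighbor and least-squares-fits a full bivariate cubic per lateral
    coordinate (>= 10 pairs required).
    """
    if mode not in ("translation", "poly3"):
        raise ConfigError(f"unknown registration mode {mode!r}")
    A, B = fiducials_A.coords, fiducials_B.coords
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise RegistrationError("need at least one fiducial per channel")

    if mode == "translation":
        translation = A.mean(axis=0) - B.mean(axis=0)
        pairs = _mutual_nearest_pairs(A, B)
        if pairs.size:
            resid = A[pairs[:, 0]] - (B[pairs[:, 1]] + translation)
            rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
        else:
            rms = float("nan")
        return RegistrationModel("translation", translation, None, rms,
                                 min(A.shape[0], B.shape[0]))

    pairs = _mutual_nearest_pairs(A, B)
    if pairs.shape[0] < 10:
        raise RegistrationError(
            f"poly3 registration needs >= 10 mutually paired fiducials, "
            f"got {pairs.shape[0]}"
        )
    src = B[pairs[:, 1]]
    dst = A[pairs[:, 0]]
    design = _poly3_design(src[:, 0], src[:, 1])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise RegistrationError("degenerate fiducial geometry (rank-deficient fit)")
    coeffs = np.empty((2, design.shape[1]))
    for k in range(2):
        coeffs[k], *_ = np.linalg.lstsq(design, dst[:, k], rcond=None)
    z_shift = np.zeros(1)
    if A.shape[1] == 3:
        z_shift = np.array([dst[:, 2].mean() - src[:, 2].mean()])
    translation = z_shift
    model = RegistrationModel("poly3", translation, coeffs, 0.0, pairs.shape[0])
    resid = dst - model.transform(src)
    model.fit_residual = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return model


def apply_registration(
    model: RegistrationModel, locs: LocalizationSet
) -> LocalizationSet:
    """Transform a channel into the reference space; metadata untouched."""
    return locs.transformed(model.transform(locs.coords))


def filter_beads(
    locs: LocalizationSet,
    radius: float = 100.0,
    frame_fraction: float = 0.9,
    n_frames: Optional[int] = None,
) -> tuple[LocalizationSet, int]:
    """Remove fiducial-bead localizations by neighbor count.

    A localization is removed iff the number of *other* localizations
    within ``radius`` (nm) is >= ``frame_fraction x n_frames``.
    ``n_frames`` defaults to ``max(frame) + 1`` when a frame column is
    present.

    Returns the filtered set and the number of removed localizations.
    """
    if n_frames is None:
        if locs.frames is None:
            raise ConfigError(
                "n_frames unknown: provide it or a frame column in the data"
            )
        n_frames = int(locs.frames.max()) + 1
    if n_frames < 1:
        raise ConfigError("n_frames must be >= 1")
    tree = cKDTree(locs.coords)
    counts = tree.query_ball_point(locs.coords, r=radius, return_length=True) - 1
    keep = counts < frame_fraction * n_frames
    frames = locs.frames[keep] if locs.frames is not None else None
    return (
        LocalizationSet(locs.coords[keep], frames, locs.channel_id),
        int((~keep).sum()),
    )
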