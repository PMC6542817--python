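"""Coordinate-based Manders and Spearman colocalization coefficients.

Both estimators operate on the pair-density scatterplots.  The Manders
coefficient of channel A is the density-weighted fraction of its
high-density localizations that survive as colocalized after the edge
correction,

.. math::

    M^A = \\frac{\\sum_{i \\in C^A} \\alpha_i \\, x_i^A}
               {\\sum_{i \\in C^A} x_i^A},
    \\qquad \\alpha_i = \\mathbb{1}[s_i^A \\in \\mathrm{corr}(C^{AB})],

with the sum running over the pre-correction high class ``C^A``.  The
Spearman coefficient per channel is the rank correlation between own
and partner normalized densities over *all* localizations of that
channel; ties are handled with average ranks, so it equals the
product-moment correlation of the ranked data.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
from scipy.stats import rankdata

from .classification import (
    ClassificationResult,
    PairDescriptorTable,
    classify,
    pair_densities,
)
from .errors import ConfigError
from .io import LocalizationSet
from .tessellation import build_tessellation


@dataclasses.dataclass
class ColocResult:
    """Outcome of a full two-channel colocalization run.

    Undefined coefficients (empty high class, zero rank variance) are
    ``None``, never silently 0.
    """

    M_A: Optional[float]
    M_B: Optional[float]
    S_A: Optional[float]
    S_B: Optional[float]
    class_counts: dict
    T: float
    edge_correction: bool
    n_A: int
    n_B: int
    labels: Optional[ClassificationResult] = None
    locs_A: Optional[LocalizationSet] = None
    locs_B: Optional[LocalizationSet] = None
    seed: Optional[int] = None

    def summary_dict(self) -> dict:
        return {
            "M_A": self.M_A,
            "M_B": self.M_B,
            "S_A": self.S_A,
            "S_B": self.S_B,
            "class_counts": self.class_counts,
            "T": self.T,
            "edge_correction": self.edge_correction,
            "n_A": self.n_A,
            "n_B": self.n_B,
            "seed": self.seed,
        }


def scatterplot(pairs: PairDescriptorTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel scatter coordinates, channel A on x and B on y for both."""
    scatter_A = np.column_stack([pairs.x_A, pairs.y_A])
    scatter_B = np.column_stack([pairs.x_B, pairs.y_B])
    return scatter_A, scatter_B


def plot_scatter(pairs: PairDescriptorTable, T: float = 1.0, axes=None):
    """Render the two density scatterplots on log-scale axes.

    The class division lines are drawn at ``delta_hat = T``.  Requires
    matplotlib; returns the two axes.
    """
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 4.2), sharex=True, sharey=True)
    for ax, scatter, title in zip(
        axes, scatterplot(pairs), ("channel A", "channel B")
    ):
        x, y = scatter[:, 0], scatter[:, 1]
        ok = (x > 0) & (y > 0)
        ax.scatter(x[ok], y[ok], s=2, alpha=0.3, linewidths=0)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.axvline(T, color="k", lw=0.8)
        ax.axhline(T, color="k", lw=0.8)
        ax.set_xlabel(r"$\hat\delta$ channel A")
        ax.set_ylabel(r"$\hat\delta$ channel B")
        ax.set_title(title)
    return axes


def manders(
    pairs: PairDescriptorTable, labels: ClassificationResult
) -> tuple[Optional[float], Optional[float]]:
    """Density-weighted colocalized fractions ``(M_A, M_B)``.

    The denominator sums own densities over the pre-correction high
    class; the indicator comes from the corrected labels.  An empty high
    class yields ``None`` with a warning.
    """
    high_A = labels.high_mask_A()
    high_B = labels.high_mask_B()
    M_A = M_B = None
    if high_A.any():
        alpha = (labels.labels_A == "AB")[high_A]
        M_A = float(np.sum(alpha * pairs.x_A[high_A]) / np.sum(pairs.x_A[high_A]))
    else:
        warnings.warn("channel A has an empty high-density class; M_A undefined")
    if high_B.any():
        alpha = (labels.labels_B == "BA")[high_B]
        M_B = float(np.sum(alpha * pairs.y_B[high_B]) / np.sum(pairs.y_B[high_B]))
    else:
        warnings.warn("channel B has an empty high-density class; M_B undefined")
    return M_A, M_B


def _rank_corr(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    if x.size < 2:
        return None
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return None
    cov = np.mean((rx - rx.mean()) * (ry - ry.mean()))
    return float(cov / (sx * sy))


def spearman(
    pairs: PairDescriptorTable,
) -> tuple[Optional[float], Optional[float]]:
    """Spearman rank correlations ``(S_A, S_B)`` over all localizations.

    Ties get average ranks; without ties this reduces to the classical
    ``1 - 6 * sum(d_i^2) / (n * (n^2 - 1))`` formula.  Degenerate inputs
    (n < 2 or zero rank variance) yield ``None``.
    """
    return _rank_corr(pairs.x_A, pairs.y_A), _rank_corr(pairs.x_B, pairs.y_B)


def run_coloc(
    locs_A: LocalizationSet,
    locs_B: LocalizationSet,
    T: float = 1.0,
    edge_correction: bool = True,
    roi=None,
    seed: Optional[int] = None,
) -> ColocResult:
    """Full pipeline: tessellate, pair, classify, and compute M and S.

    Parameters
    ----------
    locs_A, locs_B
        The two channels (same dimensionality, both non-empty).
    T
        Normalized-density threshold applied to both channels.
    edge_correction
        Apply the Delaunay/IQR correction to the AB/BA classes.
    roi
        Optional common reference box ``(lo, hi)`` for both channels;
        defaults to each channel's own bounding box.
    seed
        Recorded in the result for provenance only.
    """
    if locs_A.dim != locs_B.dim:
        raise ConfigError("channels have different dimensionality")
    locs_A = locs_A.drop_duplicates()
    locs_B = locs_B.drop_duplicates()
    model_A = build_tessellation(locs_A, roi=roi)
    model_B = build_tessellation(locs_B, roi=roi)
    pairs = pair_densities(model_A, model_B)
    labels = classify(pairs, T=T, edge_correction=edge_correction,
                      model_A=model_A, model_B=model_B)
    M_A, M_B = manders(pairs, labels)
    S_A, S_B = spearman(pairs)
    return ColocResult(
        M_A=M_A,
        M_B=M_B,
        S_A=S_A,
        S_B=S_B,
        class_counts=labels.class_counts(),
        T=T,
        edge_correction=edge_correction,
        n_A=locs_A.n,
        n_B=locs_B.n,
        labels=labels,
        locs_A=locs_A,
        locs_B=locs_B,
        seed=seed,
    )
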