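"""Pair-correlation function g(r) of a localization point pattern.

The estimator on a rectangular observation window W with n points and
intensity lambda = n / |W| is

    g(r_k) = W_k / (lambda * n * a_k)

where ``W_k`` counts ordered pairs whose separation falls in the
half-open radial bin ``[r_k, r_{k+1})`` and ``a_k = pi (r_{k+1}^2 -
r_k^2)`` is the bin annulus area. Border effects are handled either by
translation (toroidal) correction — distances computed with the
minimum-image convention on the window, which makes the estimator
unbiased for complete spatial randomness — or not at all
(``correction="none"``), which biases g low at large r.

For complete spatial randomness g(r) = 1 at all r; g > 1 indicates
clustering at that scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi import RectangleROI


@dataclass
class PairCorrelation:
    r_centers: np.ndarray   # nm
    g: np.ndarray           # dimensionless
    bin_width: float        # nm
    n_points: int
    window: RectangleROI
    correction: str
    pair_counts: np.ndarray  # ordered pair count per bin (W_k)

    @property
    def expected_pair_counts(self) -> np.ndarray:
        """E[W_k] under complete spatial randomness for this n and window."""
        lam = self.n_points / self.window.area
        edges = np.concatenate([self.r_centers - self.bin_width / 2,
                                [self.r_centers[-1] + self.bin_width / 2]])
        a_k = np.pi * np.diff(edges**2)
        return lam * self.n_points * a_k


def _pairwise_distances(x, y, window: RectangleROI, toroidal: bool) -> np.ndarray:
    dx = np.abs(x[:, None] - x[None, :])
    dy = np.abs(y[:, None] - y[None, :])
    if toroidal:
        Lx = window.x_max - window.x_min
        Ly = window.y_max - window.y_min
        dx = np.minimum(dx, Lx - dx)
        dy = np.minimum(dy, Ly - dy)
    d = np.sqrt(dx**2 + dy**2)
    iu = np.triu_indices(len(x), k=1)
    return d[iu]


def pair_correlation(
    table,
    bin_width: float,
    r_max: float,
    window: RectangleROI = None,
    correction: str = "toroidal",
) -> PairCorrelation:
    """Estimate g(r) on radial bins ``[0, bin_width), [bin_width, ...)``.

    Parameters
    ----------
    table
        LocalizationTable or (n, 2) coordinate array, nm.
    window
        Rectangular observation window containing all points; defaults to
        the bounding box. Required to be at least ``2 * r_max`` on each
        side so the toroidal correction is valid.
    correction
        ``"toroidal"`` (translation correction, unbiased under CSR) or
        ``"none"``.
    """
    if correction not in ("toroidal", "none"):
        raise ValueError("correction must be 'toroidal' or 'none'")
    X = table.xy if hasattr(table, "xy") else np.asarray(table, dtype=float)
    n = len(X)
    if n < 2:
        raise ValueError("pair correlation needs at least 2 points")
    if bin_width <= 0 or r_max <= 0:
        raise ValueError("bin_width and r_max must be positive")
    x, y = X[:, 0], X[:, 1]
    if window is None:
        window = RectangleROI(x.min(), np.nextafter(x.max(), np.inf),
                              y.min(), np.nextafter(y.max(), np.inf))
    if not window.contains(x, y).all():
        raise ValueError("window must contain all points")
    side = min(window.x_max - window.x_min, window.y_max - window.y_min)
    if r_max > side / 2:
        raise ValueError("r_max must be at most half the shorter window side")

    d = _pairwise_distances(x, y, window, toroidal=(correction == "toroidal"))
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-9]
    # half-open bins [r_k, r_{k+1})
    idx = np.floor(d / bin_width).astype(int)
    nbins = len(edges) - 1
    counts = np.bincount(idx[(idx >= 0) & (idx < nbins)], minlength=nbins).astype(float)
    counts *= 2.0  # ordered pairs

    lam = n / window.area
    a_k = np.pi * np.diff(edges**2)
    g = counts / (lam * n * a_k)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PairCorrelation(
        r_centers=centers, g=g, bin_width=bin_width, n_points=n,
        window=window, correction=correction, pair_counts=counts,
    )
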