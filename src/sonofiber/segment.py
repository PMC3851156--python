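"""Binarization and connected-component shape analysis.

The enhanced sonogram is thresholded with Otsu's method; the resulting
binary map holds the candidate fiber pixels.  Each 8-connected component
is described by the ellipse having the same normalized second central
moments as its pixel set: major-axis length L, minor-axis length omega,
aspect ratio Ar = L/omega, and major-axis orientation phi in degrees from
the downward image vertical.  These three shape measures drive the
long-thin / branched / fragment classification in the detection loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

_STRUCTURE_8 = np.ones((3, 3), dtype=bool)
_STRUCTURE_4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class Region:
    """One connected component and its equivalent-ellipse descriptors.

    ``L >= omega > 0`` and ``Ar = L / omega`` hold exactly once the
    descriptors are filled by :func:`region_shape`; ``phi`` is the
    major-axis orientation in degrees from the downward y-axis, in
    [0, 180).
    """

    label: int
    pixel_coords: np.ndarray  # (n, 2) array of (row, col)
    area: int
    centroid: Optional[Tuple[float, float]] = None
    L: Optional[float] = None
    omega: Optional[float] = None
    Ar: Optional[float] = None
    phi: Optional[float] = None


def otsu_threshold(image: np.ndarray, n_levels: int = 256) -> float:
    """Otsu's optimal threshold on a ``n_levels``-bin histogram.

    The histogram spans [min, max] of the image with uniform bins; the
    returned threshold is the center of the bin t maximizing the
    between-class variance w0*w1*(mu0 - mu1)^2 of the classes {<= t} and
    {> t}.  Ties are broken toward the smallest level.  A constant image
    has no separating threshold and raises ``ValueError``.
    """
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        raise ValueError("no threshold separates a constant image")
    counts, edges = np.histogram(image.ravel(), bins=n_levels, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = _otsu_index(counts, centers)
    return float(centers[idx])


def _otsu_index(counts: np.ndarray, levels: np.ndarray) -> int:
    """Index of the level maximizing between-class variance (smallest tie)."""
    counts = np.asarray(counts, dtype=float)
    levels = np.asarray(levels, dtype=float)
    total = counts.sum()
    w0 = np.cumsum(counts)
    mu_cum = np.cumsum(counts * levels)
    mu_total = mu_cum[-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_total - mu_cum) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.where((w0 > 0) & (w1 > 0), var_between, -np.inf)
    if not np.any(np.isfinite(var_between)):
        raise ValueError("no threshold separates a constant image")
    return int(np.argmax(var_between))  # argmax returns the first (smallest) tie


def binarize(image: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean map of candidate fiber pixels: strictly above the threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.asarray(image) > threshold


def label_regions(mask: np.ndarray, connectivity: int = 8):
    """Partition true pixels into connected components.

    8-connectivity by default: fascicle traces are thin and often
    diagonal, so 4-connectivity would fragment them.  Labels are assigned
    1..K in raster first-encounter order.  Descriptors are left unfilled;
    see :func:`region_shape`.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCTURE_8 if connectivity == 8 else _STRUCTURE_4
    labeled, n = ndimage.label(np.asarray(mask, dtype=bool), structure=structure)
    regions = []
    if n == 0:
        return regions
    # one pass over all foreground pixels, grouped by label
    rows, cols = np.nonzero(labeled)
    labels = labeled[rows, cols]
    order = np.argsort(labels, kind="stable")
    rows, cols, labels = rows[order], cols[order], labels[order]
    boundaries = np.searchsorted(labels, np.arange(1, n + 2))
    for lab in range(1, n + 1):
        sl = slice(boundaries[lab - 1], boundaries[lab])
        coords = np.stack([rows[sl], cols[sl]], axis=1)
        regions.append(Region(label=lab, pixel_coords=coords, area=len(coords)))
    return regions


def region_shape(region: Region) -> Region:
    """Fill a region's equivalent-ellipse descriptors in place.

    The second central moments of the pixel coordinates (per unit area)
    are augmented by 1/12 on each diagonal term — the variance of a unit
    square pixel — so a single pixel has a well-defined isotropic ellipse
    and thin bars keep finite aspect ratios.  With eigenvalues
    ``e_max >= e_min`` of the corrected moment matrix,
    ``L = 4 sqrt(e_max)`` and ``omega = 4 sqrt(e_min)``.
    """
    coords = np.asarray(region.pixel_coords, dtype=float)
    if coords.size == 0:
        raise ValueError("region must be non-empty")
    r, c = coords[:, 0], coords[:, 1]
    n = len(coords)
    r0, c0 = r.mean(), c.mean()
    dr, dc = r - r0, c - c0
    mrr = (dr * dr).sum() / n + 1.0 / 12.0
    mcc = (dc * dc).sum() / n + 1.0 / 12.0
    mrc = (dr * dc).sum() / n

    half_trace = 0.5 * (mrr + mcc)
    disc = np.sqrt(0.25 * (mrr - mcc) ** 2 + mrc * mrc)
    e_max = half_trace + disc
    e_min = max(half_trace - disc, 0.0)

    region.centroid = (float(r0), float(c0))
    region.L = float(4.0 * np.sqrt(e_max))
    region.omega = float(4.0 * np.sqrt(e_min))
    region.Ar = region.L / region.omega

    if disc <= 1e-12 * max(e_max, 1e-30):
        # isotropic moment matrix: orientation undefined; deterministic tie-break
        region.phi = 0.0
    else:
        # eigenvector of e_max in (row, col) coordinates
        if abs(mrc) > 1e-30:
            v = np.array([e_max - mcc, mrc])
        else:
            v = np.array([1.0, 0.0]) if mrr >= mcc else np.array([0.0, 1.0])
        # angle from the downward y-axis (row direction), folded to [0, 180);
        # positive angles rotate toward decreasing column, matching the
        # Hough-angle convention in sonofiber.detect
        phi = np.degrees(np.arctan2(-v[1], v[0])) % 180.0
        region.phi = float(phi)
    return region
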