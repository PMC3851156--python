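"""Iterative longest-region-first line detection on the binary map.

Candidate fiber regions fall into three patterns: long thin single
fibers, long branched regions where several fibers adhere, and short
fragments of a partially imaged ("broken") fiber.  The detector loops:

1. set thresholds T1 (aspect ratio), T2 (width, px), T3 (last-to-first
   length ratio) and N (max lines per frame); n = 1;
2. extract the region with the largest equivalent-ellipse length L and
   measure its Ar, omega, L;
3. if Ar > T1 and omega < T2 the region is a single fiber and its
   orientation is read off the ellipse major axis (cheap); otherwise it
   is branched and one line is extracted by a Hough transform restricted
   to that region's pixels;
4. pixels within half the removal width of the detected line are removed
   map-wide, consuming noise near the line and collinear fragments of
   the same broken fiber;
5. stop when n = N or L^n < L^1 * T3, else repeat.

In practice almost all regions take the ellipse path, which is why this
framework is fast compared with voting over every candidate pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from .enhance import VesselnessParams, mvef
from .segment import Region, binarize, label_regions, otsu_threshold, region_shape

logger = logging.getLogger(__name__)

#: Maximum lines per frame suited to reduced muscle architecture
#: (e.g. imaging of an aged triceps surae with fewer visible patterns).
N_REDUCED_ARCHITECTURE = 4


@dataclass(frozen=True)
class DetectorConfig:
    """All tunable parameters of the detection pipeline.

    Attributes
    ----------
    T1 : float
        Aspect-ratio threshold; a region with ``Ar > T1`` (and narrow
        enough) is treated as a single fiber.
    T2 : float
        Width threshold in pixels; ``omega < T2`` is required for the
        ellipse path.
    T3 : float
        Last-to-first length ratio in (0, 1]; detection stops once the
        current region's length drops below ``T3 * L^1``.
    N : int
        Maximum number of lines per frame.  Default 7 (skin, bone, two
        aponeuroses and fascicles in between); use
        :data:`N_REDUCED_ARCHITECTURE` when fewer patterns are expected.
    removal_width : int
        Odd strip width in pixels removed around each detected line.
    theta_step, rho_step : float
        Hough accumulator resolutions (degrees, pixels).
    connectivity : int
        4 or 8 for connected components.
    drop_terminal_short_line : bool
        The length-ratio stop test runs after a line is recorded; by
        default that terminal short line stays in the output.  Set True
        to drop it.
    """

    T1: float = 5.0
    T2: float = 30.0
    T3: float = 0.10
    N: int = 7
    removal_width: int = 17
    theta_step: float = 1.0
    rho_step: float = 1.0
    connectivity: int = 8
    drop_terminal_short_line: bool = False
    mvef: VesselnessParams = field(default_factory=VesselnessParams)
    seed: int = 0

    def __post_init__(self):
        if not self.T1 > 0 or not self.T2 > 0:
            raise ValueError("T1 and T2 must be > 0")
        if not 0 < self.T3 <= 1:
            raise ValueError("T3 must be in (0, 1]")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.removal_width < 1 or self.removal_width % 2 == 0:
            raise ValueError("removal_width must be odd and >= 1")
        if not self.theta_step > 0 or not self.rho_step > 0:
            raise ValueError("Hough resolutions must be > 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class DetectedLine:
    """One detected fiber line.

    ``angle_deg`` is the MFO in the NIH-Image convention (degrees from
    the downward vertical, in [0, 180)); ``method`` records whether the
    angle came from the ellipse major axis or from a Hough transform on
    the source region; ``votes`` is the Hough peak count (hough only).
    """

    order: int
    angle_deg: float
    method: str  # "ellipse" | "hough"
    anchor: Tuple[float, float]  # (row, col) on the line
    L: float
    omega: float
    Ar: float
    region_label: int
    votes: Optional[int] = None


@dataclass
class FrameResult:
    """Everything the pipeline produced for one frame."""

    enhanced: np.ndarray
    binary_map: np.ndarray
    lines: List[DetectedLine]
    config: DetectorConfig


def classify_region(Ar: float, omega: float, config: DetectorConfig) -> str:
    """Route a region: ``"ellipse"`` iff Ar > T1 and omega < T2 (strict)."""
    return "ellipse" if (Ar > config.T1 and omega < config.T2) else "hough"


def hough_line(
    pixels: np.ndarray,
    image_diag: float,
    theta_step: float = 1.0,
    rho_step: float = 1.0,
) -> Tuple[float, float, int]:
    """Peak of the line accumulator over one region's pixels.

    Uses the normal parameterization ``rho = col*cos(theta) +
    row*sin(theta)`` with theta sampled on [0, 180) at ``theta_step`` and
    rho binned on [-diag, diag] at ``rho_step``.  Only the given pixels
    vote — never the whole map.  Returns ``(theta_deg, rho, votes)`` of
    the global accumulator maximum; ties go to the smallest theta, then
    the smallest rho.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.size == 0:
        raise ValueError("hough_line requires a non-empty pixel set")
    rows, cols = pixels[:, 0], pixels[:, 1]
    thetas = np.arange(0.0, 180.0, theta_step)
    n_rho = int(np.floor(2 * image_diag / rho_step)) + 1

    best = (-1, 0, 0)  # votes, theta index, rho index
    for ti, theta in enumerate(thetas):
        t = np.radians(theta)
        rho = cols * np.cos(t) + rows * np.sin(t)
        idx = np.rint((rho + image_diag) / rho_step).astype(np.intp)
        np.clip(idx, 0, n_rho - 1, out=idx)
        counts = np.bincount(idx, minlength=n_rho)
        ri = int(np.argmax(counts))  # first max -> smallest rho
        v = int(counts[ri])
        if v > best[0]:
            best = (v, ti, ri)
    votes, ti, ri = best
    theta_star = float(thetas[ti])
    rho_star = float(ri * rho_step - image_diag)
    return theta_star, rho_star, votes


def line_angle_from_theta(theta_deg: float) -> float:
    """Convert a Hough normal angle to the NIH angle convention.

    The line runs perpendicular to its normal, along the unit vector
    ``(d_col, d_row) = (-sin theta, cos theta)``; the returned value is
    the unsigned angle between that direction and the downward vertical
    ``(0, +1)``, folded into [0, 180).
    """
    if not 0 <= theta_deg < 180:
        raise ValueError("theta must lie in [0, 180)")
    t = np.radians(theta_deg)
    d_col, d_row = -np.sin(t), np.cos(t)
    # signed angle from the down vector, positive toward decreasing column;
    # the same handedness sonofiber.segment uses for the ellipse phi
    angle = np.degrees(np.arctan2(-d_col, d_row))
    return float(angle % 180.0)


def ellipse_angle_to_mfo(phi: float) -> float:
    """Adapt a region's ellipse orientation to the output convention.

    :func:`sonofiber.segment.region_shape` already measures phi from the
    downward y-axis, so this is the identity; it exists as the single
    seam to adapt should an alternate phi convention be plugged in.
    """
    return float(phi)


def remove_line_pixels(
    mask: np.ndarray, line: DetectedLine, removal_width: int
) -> np.ndarray:
    """Clear true pixels within the strip around a detected line.

    Every true pixel whose perpendicular distance to the infinite line
    through ``line.anchor`` at ``line.angle_deg`` is at most
    ``(removal_width - 1) / 2`` is set false, across the whole map — so
    collinear fragments of a broken fiber are consumed along with noise
    near the line.  Returns a new map; the input is not mutated.
    """
    if removal_width < 1 or removal_width % 2 == 0:
        raise ValueError("removal_width must be odd and >= 1")
    mask = np.asarray(mask, dtype=bool)
    half = (removal_width - 1) / 2.0
    a = np.radians(line.angle_deg)
    d_row, d_col = np.cos(a), -np.sin(a)  # line direction in (row, col)
    ar, ac = line.anchor
    rows, cols = np.nonzero(mask)
    # 2-D cross product of (pixel - anchor) with the direction = perp distance
    dist = np.abs((rows - ar) * d_col - (cols - ac) * d_row)
    hit = dist <= half + 1e-9  # tolerate rounding at the exact strip edge
    out = mask.copy()
    out[rows[hit], cols[hit]] = False
    return out


def _pick_longest(regions: List[Region]) -> Region:
    """Largest L; ties broken by larger area, then smaller label."""
    return max(regions, key=lambda g: (g.L, g.area, -g.label))


def detect_lines(mask: np.ndarray, config: DetectorConfig = None) -> List[DetectedLine]:
    """Run the detection loop on a binary candidate map.

    Returns the ordered list of detected lines (at most ``config.N``).
    Deterministic for fixed input and config; an empty map yields an
    empty list.
    """
    if config is None:
        config = DetectorConfig()
    current = np.asarray(mask, dtype=bool)
    lines: List[DetectedLine] = []
    L1 = None
    diag = float(np.hypot(*current.shape))

    for n in range(1, config.N + 1):
        regions = label_regions(current, connectivity=config.connectivity)
        if not regions:
            break
        for g in regions:
            region_shape(g)
        g = _pick_longest(regions)
        if L1 is None:
            L1 = g.L

        method = classify_region(g.Ar, g.omega, config)
        if method == "ellipse":
            line = DetectedLine(
                order=n,
                angle_deg=ellipse_angle_to_mfo(g.phi),
                method="ellipse",
                anchor=g.centroid,
                L=g.L,
                omega=g.omega,
                Ar=g.Ar,
                region_label=g.label,
            )
        else:
            theta, rho, votes = hough_line(
                g.pixel_coords, diag, config.theta_step, config.rho_step
            )
            # anchor = foot of the perpendicular from the centroid onto the line
            t = np.radians(theta)
            n_row, n_col = np.sin(t), np.cos(t)
            proj = g.centroid[1] * n_col + g.centroid[0] * n_row
            anchor = (
                g.centroid[0] + (rho - proj) * n_row,
                g.centroid[1] + (rho - proj) * n_col,
            )
            line = DetectedLine(
                order=n,
                angle_deg=line_angle_from_theta(theta),
                method="hough",
                anchor=anchor,
                L=g.L,
                omega=g.omega,
                Ar=g.Ar,
                region_label=g.label,
                votes=votes,
            )

        terminal_short = g.L < L1 * config.T3
        if not (terminal_short and config.drop_terminal_short_line):
            lines.append(line)
        if terminal_short:
            break
        current = remove_line_pixels(current, line, config.removal_width)
    return lines


def run_pipeline(image: np.ndarray, config: DetectorConfig = None) -> FrameResult:
    """Enhance, binarize and detect on one grayscale frame.

    A blank (constant) enhanced frame produces zero lines with a logged
    warning instead of an exception, so sequence processing survives
    empty frames.
    """
    if config is None:
        config = DetectorConfig()
    enhanced = mvef(image, config.mvef)
    try:
        threshold = otsu_threshold(enhanced)
    except ValueError:
        logger.warning("enhanced frame is constant; no lines detected")
        return FrameResult(
            enhanced=enhanced,
            binary_map=np.zeros(enhanced.shape, dtype=bool),
            lines=[],
            config=config,
        )
    mask = binarize(enhanced, threshold)
    lines = detect_lines(mask, config)
    return FrameResult(enhanced=enhanced, binary_map=mask, lines=lines, config=config)
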