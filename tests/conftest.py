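"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the implementation's code paths:
Otsu by exhaustive search over every candidate level, ellipse moments by
an explicit covariance matrix fed to ``numpy.linalg.eigh``, and the
Hough peak by a dense accumulator built with plain Python loops.
"""

import numpy as np
import pytest

from sonofiber.synthfix import BarSpec, SceneSpec, render_scene


def brute_otsu_index(counts, levels):
    """Exhaustive between-class-variance maximization; smallest-level tie."""
    counts = np.asarray(counts, dtype=float)
    levels = np.asarray(levels, dtype=float)
    total = counts.sum()
    best_idx, best_var = None, -np.inf
    for t in range(len(levels)):
        w0 = counts[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: t + 1] * levels[: t + 1]).sum() / w0
        mu1 = (counts[t + 1 :] * levels[t + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-12 * max(abs(var), 1.0):
            best_var, best_idx = var, t
    return best_idx


def oracle_ellipse(coords):
    """(L, omega, phi_deg) from the corrected coordinate covariance matrix."""
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    cov[0, 0] += 1.0 / 12.0
    cov[1, 1] += 1.0 / 12.0
    evals, evecs = np.linalg.eigh(cov)
    L = 4.0 * np.sqrt(evals[1])
    omega = 4.0 * np.sqrt(evals[0])
    v = evecs[:, 1]  # (row, col) eigenvector of the larger eigenvalue
    phi = np.degrees(np.arctan2(-v[1], v[0])) % 180.0
    return L, omega, phi


def brute_hough(pixels, diag, theta_step=1.0, rho_step=1.0):
    """Dense accumulator built pixel by pixel; smallest-theta/rho tie-break."""
    thetas = np.arange(0.0, 180.0, theta_step)
    n_rho = int(np.floor(2 * diag / rho_step)) + 1
    acc = np.zeros((len(thetas), n_rho), dtype=int)
    for r, c in pixels:
        for ti, theta in enumerate(thetas):
            t = np.radians(theta)
            rho = c * np.cos(t) + r * np.sin(t)
            ri = int(round((rho + diag) / rho_step))
            ri = min(max(ri, 0), n_rho - 1)
            acc[ti, ri] += 1
    best = (-1, None, None)
    for ti in range(len(thetas)):
        for ri in range(n_rho):
            if acc[ti, ri] > best[0]:
                best = (acc[ti, ri], ti, ri)
    votes, ti, ri = best
    return float(thetas[ti]), float(ri * rho_step - diag), votes


def angle_diff(a, b):
    """Unsigned difference between two axial angles, in [0, 90]."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


@pytest.fixture
def single_bar_scene():
    """A clean diagonal fascicle surrogate at 25 degrees."""
    return SceneSpec(
        shape=(160, 160),
        bars=(BarSpec(angle_deg=25.0, center=(80, 80), length=100, width=5),),
        seed=3,
    )


@pytest.fixture
def single_bar_frame(single_bar_scene):
    frame, truth = render_scene(single_bar_scene)
    return frame, truth


@pytest.fixture
def nine_bar_scene():
    """Nine identical, well-separated horizontal bars."""
    bars = tuple(
        BarSpec(angle_deg=90.0, center=(28 + 30 * i, 120), length=180, width=5)
        for i in range(9)
    )
    return SceneSpec(shape=(300, 240), bars=bars, seed=11)
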