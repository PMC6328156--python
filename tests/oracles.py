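"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a different route than the package
(dense polygonal boundaries, exhaustive pair counting, closed forms), so
agreement is evidence of correctness rather than self-consistency.
"""

from __future__ import annotations

import math

import numpy as np


def polygon_ray_distance(ellipse, origin, direction, n_vertices: int = 20000) -> float:
    """Ray-to-boundary distance against a dense polygonal boundary.

    Approximates the ellipse by an ``n_vertices``-gon and intersects the
    ray with its edges; the sagitta error is far below 1e-3 px at the
    default density for disc-scale ellipses.
    """
    origin = np.asarray(origin, dtype=float)
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    V = ellipse.boundary_points(n_vertices) - origin
    x = V @ u
    y = V @ np.array([-u[1], u[0]])
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    straddle = (y <= 0) != (y2 <= 0)
    s = y[straddle] / (y[straddle] - y2[straddle])
    xint = x[straddle] + s * (x2[straddle] - x[straddle])
    ahead = xint[xint > 0]
    assert ahead.size >= 1, "origin must be inside the polygon"
    return float(ahead.min())


def polygon_vertical_chord(ellipse, x0: float, n_vertices: int = 20000) -> float:
    """Length of the vertical-line chord at ``x = x0`` against the polygon."""
    V = ellipse.boundary_points(n_vertices)
    x, y = V[:, 0] - x0, V[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    straddle = (x <= 0) != (x2 <= 0)
    s = x[straddle] / (x[straddle] - x2[straddle])
    yint = y[straddle] + s * (y2[straddle] - y[straddle])
    assert yint.size >= 2, "line must cross the polygon"
    return float(yint.max() - yint.min())


def pairwise_concordance_auc(scores, labels) -> float:
    """Exhaustive pairwise AUROC with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def balanced_oneway_reml(Y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form REML for the balanced one-way random-effects layout.

    ``Y`` is (eyes, directions).  Returns (sigma_d^2, sigma_e^2, mu):
    within mean square, and the between/within mean-square contrast.
    """
    a, m = Y.shape
    ybar_i = Y.mean(axis=1)
    ybar = Y.mean()
    msw = float(((Y - ybar_i[:, None]) ** 2).sum() / (a * (m - 1)))
    msb = float(m * ((ybar_i - ybar) ** 2).sum() / (a - 1))
    return (msb - msw) / m, msw, float(ybar)


def scalar_discriminant_log_odds(
    y: float, mu_g: float, mu_h: float, sigma_d: float, sigma_e: float,
    p_g: float, p_h: float,
) -> float:
    """Closed-form single-direction Gaussian discriminant log odds."""
    v = sigma_d**2 + sigma_e**2
    return math.log(p_g / p_h) + 0.5 * ((y - mu_h) ** 2 - (y - mu_g) ** 2) / v


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Standard error of an empirical AUROC at a given true value."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return math.sqrt(var)


def random_valid_segmentation(rng: np.random.Generator):
    """A random cup/disc ellipse pair with the cup centre inside the disc."""
    from pcdr import DiscSegmentation, Ellipse

    while True:
        a_d = rng.uniform(60.0, 140.0)
        b_d = a_d * rng.uniform(0.6, 1.0)
        disc = Ellipse(rng.uniform(100, 500), rng.uniform(100, 500), a_d, b_d,
                       rng.uniform(0.0, math.pi))
        s = rng.uniform(0.3, 0.7)
        axes = np.sort([s * a_d * rng.uniform(0.9, 1.1), s * b_d * rng.uniform(0.9, 1.1)])[::-1]
        off = rng.uniform(-0.15, 0.15, 2) * b_d
        cup = Ellipse(disc.center_x + off[0], disc.center_y + off[1],
                      axes[0], axes[1], rng.uniform(0.0, math.pi))
        if not disc.contains((cup.center_x, cup.center_y)):
            continue
        laterality = "right" if rng.random() < 0.5 else "left"
        try:
            return DiscSegmentation("rand", laterality, cup, disc)
        except ValueError:
            continue
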