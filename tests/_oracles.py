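"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the Mann-Whitney oracle
enumerates every rank assignment, the Welch oracle is the textbook formula
in plain floats, and the centroid oracle rasterizes the polygon on a fine
grid.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats as sps
from scipy.special import stdtr


def mwu_enumeration(a, b, alternative: str) -> tuple[float, float]:
    """Exact Mann-Whitney U_a and p by enumerating all C(n, n_a) assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    ranks = sps.rankdata(pooled)
    na, n = len(a), len(pooled)
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2)
    us = np.array(
        [
            ranks[list(idx)].sum() - na * (na + 1) / 2
            for idx in combinations(range(n), na)
        ]
    )
    eps = 1e-12
    p_ge = float(np.mean(us >= u_obs - eps))
    p_le = float(np.mean(us <= u_obs + eps))
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return u_obs, p


def welch_formula(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Welch two-sample t by the closed-form textbook expressions."""
    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    cdf = stdtr(df, t)
    if alternative == "greater":
        p = 1.0 - cdf
    elif alternative == "less":
        p = cdf
    else:
        p = 2.0 * min(cdf, 1.0 - cdf)
    return t, p


def raster_centroid(vertices, resolution: float = 0.02) -> tuple[float, float]:
    """Polygon centroid by brute-force point-in-polygon rasterization."""
    from matplotlib.path import Path

    v = np.asarray(vertices, dtype=float)
    x0, y0 = v.min(axis=0) - 1
    x1, y1 = v.max(axis=0) + 1
    xs = np.arange(x0 + resolution / 2, x1, resolution)
    ys = np.arange(y0 + resolution / 2, y1, resolution)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = Path(v).contains_points(pts)
    hit = pts[inside]
    return float(hit[:, 0].mean()), float(hit[:, 1].mean())


def random_simple_polygon(rng: np.random.Generator, n_vertices: int = 8):
    """Star-shaped (hence simple) polygon with random radii and center."""
    # one vertex per angular sector with bounded jitter: consecutive gaps stay
    # below pi, so the center lies in the kernel and the polygon is simple
    jitter = rng.uniform(0.3, 0.7, size=n_vertices)
    angles = 2 * np.pi * (np.arange(n_vertices) + jitter) / n_vertices
    radii = rng.uniform(1.0, 5.0, size=n_vertices)
    cx, cy = rng.uniform(-10, 10, size=2)
    return [
        (cx + r * np.cos(t), cy + r * np.sin(t)) for r, t in zip(radii, angles)
    ]
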