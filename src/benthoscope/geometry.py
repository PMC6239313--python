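"""Exact minimum enclosing circle of a point set (Welzl's algorithm).

Used to turn connected regions of "interesting" mask pixels into circle
annotation candidates.  The implementation is the iterative move-to-front
variant, which is exact and runs in expected linear time after a seeded
deterministic shuffle.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["min_enclosing_circle"]

_EPS = 1e-9


def _circle_two(p: tuple[float, float], q: tuple[float, float]):
    cx = (p[0] + q[0]) / 2.0
    cy = (p[1] + q[1]) / 2.0
    r = math.dist(p, q) / 2.0
    return cx, cy, r


def _circle_three(p, q, s):
    ax, ay = p
    bx, by = q
    cx, cy = s
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < _EPS:  # collinear: fall back to widest pair
        pairs = [_circle_two(p, q), _circle_two(p, s), _circle_two(q, s)]
        return max(pairs, key=lambda c: c[2])
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    return ux, uy, math.dist((ux, uy), p)


def _inside(c, p) -> bool:
    return math.dist((c[0], c[1]), p) <= c[2] + _EPS * (1.0 + c[2])


def min_enclosing_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Smallest circle ``(cx, cy, r)`` covering all ``(x, y)`` points.

    Exact for degenerate inputs: one point gives radius 0, collinear points
    give the diameter of the extreme pair.  Deterministic (fixed shuffle).
    """
    pts = [tuple(map(float, p)) for p in np.atleast_2d(np.asarray(points, dtype=float))]
    if not pts:
        raise ValueError("point set is empty")
    rng = np.random.default_rng(0)
    order = rng.permutation(len(pts))
    pts = [pts[i] for i in order]

    c = (pts[0][0], pts[0][1], 0.0)
    for i, p in enumerate(pts):
        if _inside(c, p):
            continue
        c = (p[0], p[1], 0.0)
        for j in range(i):
            q = pts[j]
            if _inside(c, q):
                continue
            c = _circle_two(p, q)
            for k in range(j):
                s = pts[k]
                if _inside(c, s):
                    continue
                c = _circle_three(p, q, s)
    return c
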