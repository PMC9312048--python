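"""Independent oracles used by the tests.

Deliberately written with different algebra and code paths than the package:
pure-Python per-segment ray intersection, a direct sums-of-squares
repeated-measures decomposition, and closed forms.
"""

import math

import numpy as np


def brute_ray_distances(origin, theta_deg, vertices, merge_tol=1e-9):
    """All crossing distances of the ray (angle from +x, CCW) with a polyline.

    Per-segment solve of the 2x2 linear system by Cramer's rule, in a plain
    Python loop; near-coincident crossings are merged like the implementation
    specifies.
    """
    ox, oy = origin
    th = math.radians(theta_deg)
    dx, dy = math.cos(th), math.sin(th)
    hits = []
    for (x1, y1), (x2, y2) in zip(vertices[:-1], vertices[1:]):
        sx, sy = x2 - x1, y2 - y1
        det = dx * (-sy) - (-sx) * dy
        if abs(det) < 1e-15:
            continue
        bx, by = x1 - ox, y1 - oy
        t = (bx * (-sy) - (-sx) * by) / det
        u = (dx * by - dy * bx) / det
        if t > merge_tol and -1e-12 <= u <= 1.0 + 1e-12:
            hits.append(t)
    hits.sort()
    merged = []
    for t in hits:
        if not merged or t - merged[-1] > merge_tol:
            merged.append(t)
    return merged


def two_way_within_anova_ss(y):
    """Two-way fully within-subject ANOVA by direct sums of squares.

    ``y`` has shape (subjects, a_levels, b_levels), one observation per cell.
    Returns {effect: (F, df1, df2)} for effects 'A', 'B', 'A*B', each tested
    against its own subject-interaction error term.
    """
    y = np.asarray(y, dtype=float)
    n, a, b = y.shape
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_s = a * b * np.sum((m_s - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_sab = ss_total - ss_s - ss_a - ss_b - ss_ab - ss_sa - ss_sb

    out = {}
    out["A"] = (float((ss_a / (a - 1)) / (ss_sa / ((a - 1) * (n - 1)))),
                a - 1, (a - 1) * (n - 1))
    out["B"] = (float((ss_b / (b - 1)) / (ss_sb / ((b - 1) * (n - 1)))),
                b - 1, (b - 1) * (n - 1))
    out["A*B"] = (float((ss_ab / ((a - 1) * (b - 1))) / (ss_sab / ((a - 1) * (b - 1) * (n - 1)))),
                  (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1))
    return out


def ellipse_polar_radius(a, b, theta_deg):
    """Closed-form centre-to-boundary distance of an ellipse at a polar angle."""
    th = math.radians(theta_deg)
    return a * b / math.sqrt((b * math.cos(th)) ** 2 + (a * math.sin(th)) ** 2)
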