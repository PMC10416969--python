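"""Independent point-in-polygon oracle for the Clarke error grid.

Builds the five zone regions as shapely geometry — half-plane intersections
of the canonical zone boundary lines, made mutually exclusive by the A, E,
C, D, B priority — and classifies points geometrically.  Shares no code
with :func:`cgmcal.evaluation.clarke_zones`.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

_EXT = 2000.0  # generous bounding extent, mg/dL


def _halfplane(a: float, b: float, c: float) -> Polygon:
    """Region a*x + b*y <= c as a large polygon."""
    # pick two far-apart points on the line, offset into the feasible side
    if abs(b) >= abs(a):
        xs = np.array([-_EXT, _EXT])
        ys = (c - a * xs) / b
        p1, p2 = (xs[0], ys[0]), (xs[1], ys[1])
        normal = np.array([a, b])
    else:
        ys = np.array([-_EXT, _EXT])
        xs = (c - b * ys) / a
        p1, p2 = (xs[0], ys[0]), (xs[1], ys[1])
        normal = np.array([a, b])
    normal = normal / np.linalg.norm(normal)
    off = -normal * 4 * _EXT  # into the <= side
    p3 = (p2[0] + off[0], p2[1] + off[1])
    p4 = (p1[0] + off[0], p1[1] + off[1])
    return Polygon([p1, p2, p3, p4])


def build_zone_polygons(window: float = 460.0) -> dict[str, shapely.Geometry]:
    """Exclusive zone regions inside the square (0, window)^2."""
    w = box(0.0, 0.0, window, window)

    # x = reference, y = estimate
    zone_a = unary_union(
        [
            box(0.0, 0.0, 70.0, 70.0),
            # 0.8x <= y <= 1.2x
            _halfplane(0.8, -1.0, 0.0).intersection(_halfplane(-1.2, 1.0, 0.0)),
        ]
    ).intersection(w)
    zone_e_raw = unary_union(
        [
            _halfplane(-1.0, 0.0, -180.0).intersection(_halfplane(0.0, 1.0, 70.0)),
            _halfplane(1.0, 0.0, 70.0).intersection(_halfplane(0.0, -1.0, -180.0)),
        ]
    ).intersection(w)
    zone_c_raw = unary_union(
        [
            # 70 <= x <= 290, y >= x + 110
            _halfplane(-1.0, 0.0, -70.0)
            .intersection(_halfplane(1.0, 0.0, 290.0))
            .intersection(_halfplane(1.0, -1.0, -110.0)),
            # 130 <= x <= 180, y <= (7/5)x - 182
            _halfplane(-1.0, 0.0, -130.0)
            .intersection(_halfplane(1.0, 0.0, 180.0))
            .intersection(_halfplane(-7.0 / 5.0, 1.0, -182.0)),
        ]
    ).intersection(w)
    zone_d_raw = unary_union(
        [
            # x >= 240, 70 <= y <= 180
            _halfplane(-1.0, 0.0, -240.0)
            .intersection(_halfplane(0.0, -1.0, -70.0))
            .intersection(_halfplane(0.0, 1.0, 180.0)),
            # x <= 175/3, 70 <= y <= 180
            _halfplane(1.0, 0.0, 175.0 / 3.0)
            .intersection(_halfplane(0.0, -1.0, -70.0))
            .intersection(_halfplane(0.0, 1.0, 180.0)),
            # 175/3 <= x <= 70, y >= (6/5)x
            _halfplane(-1.0, 0.0, -175.0 / 3.0)
            .intersection(_halfplane(1.0, 0.0, 70.0))
            .intersection(_halfplane(6.0 / 5.0, -1.0, 0.0)),
        ]
    ).intersection(w)

    zone_e = zone_e_raw.difference(zone_a)
    zone_c = zone_c_raw.difference(zone_a).difference(zone_e)
    zone_d = zone_d_raw.difference(zone_a).difference(zone_e).difference(zone_c)
    zone_b = (
        w.difference(zone_a).difference(zone_e).difference(zone_c).difference(zone_d)
    )
    return {"A": zone_a, "B": zone_b, "C": zone_c, "D": zone_d, "E": zone_e}


def oracle_zones(references, estimates, window: float = 460.0):
    """Zone membership matrix and labels from the polygon oracle.

    Returns ``(labels, hits)`` where ``hits[i, j]`` says whether pair i lies
    in zone j (zones ordered A–E); points on shared boundaries may register
    in more than one zone and get the priority-first label.
    """
    polys = build_zone_polygons(window)
    x = np.asarray(references, dtype=float)
    y = np.asarray(estimates, dtype=float)
    order = ["A", "B", "C", "D", "E"]
    hits = np.column_stack(
        [shapely.contains_xy(shapely.prepare(polys[z]) or polys[z], x, y) for z in order]
    )
    labels = np.full(x.shape, "?", dtype=object)
    for z in ["A", "E", "C", "D", "B"]:  # same priority as the rule set
        j = order.index(z)
        labels[(labels == "?") & hits[:, j]] = z
    return labels.astype(str), hits
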