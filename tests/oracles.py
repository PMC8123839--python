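"""Independent oracles used by the test suite.

These deliberately re-derive results along a different computational path
than the package: exhaustive search instead of sorted-array bisection for
pairing, and explicit polygon membership (shapely) instead of piecewise
inequalities for the Clarke grid.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import Polygon, box


def brute_force_match(
    serum_times: list[float], cgm_times: list[float], window: float
) -> list[tuple[int, int]]:
    """Exhaustive all-pairs nearest matching with the pipeline's semantics.

    Serum draws processed in time order; each CGM reading used at most once;
    |Δt| ≤ window inclusive; ties at equal |Δt| go to the earlier CGM time.
    Returns (serum_index, cgm_index) pairs in original index space.
    """
    order = sorted(range(len(serum_times)), key=lambda i: serum_times[i])
    consumed: set[int] = set()
    out = []
    for i in order:
        t = serum_times[i]
        best = None
        best_key = None
        for j, ct in enumerate(cgm_times):
            if j in consumed:
                continue
            d = abs(ct - t)
            if d > window:
                continue
            key = (d, ct)  # smaller distance first, then earlier reading
            if best_key is None or key < best_key:
                best, best_key = j, key
        if best is not None:
            consumed.add(best)
            out.append((i, best))
    return out


# --- Clarke zone polygons over [0, 400]^2 (reference = x, device = y) ---------

_X70 = 175.0 / 3.0  # reference where device = 70 meets device = 1.2*reference


def clarke_polygons() -> dict[str, shapely.Geometry]:
    """Zones A, C, D, E as explicit polygons; B is the remaining area."""
    a = shapely.union(
        box(0, 0, 70, 70),
        Polygon([(0, 0), (400, 320), (400, 400), (400 / 1.2, 400)]),  # 0.8x <= y <= 1.2x
    )
    c = shapely.union(
        Polygon([(70, 180), (290, 400), (70, 400)]),  # y >= x + 110
        Polygon([(130, 0), (180, 0), (180, 70)]),  # y <= 1.4x - 182
    )
    d = shapely.union(
        box(240, 70, 400, 180),
        Polygon([(0, 70), (_X70, 70), (70, 84), (70, 180), (0, 180)]),
    )
    e = shapely.union(box(180, 0, 400, 70), box(0, 180, 70, 400))
    full = box(0, 0, 400, 400)
    b = full.difference(shapely.union_all([a, c, d, e]))
    return {"A": a, "B": b, "C": c, "D": d, "E": e}


def clarke_zone_by_polygon(points: np.ndarray) -> np.ndarray:
    """Zone labels for an (n, 2) array of off-boundary (reference, device) points."""
    polys = clarke_polygons()
    pts = shapely.points(points)
    labels = np.full(len(points), "B", dtype="U1")
    for z in ("A", "E", "C", "D"):
        inside = shapely.contains(polys[z], pts)
        labels[inside & (labels == "B")] = z
    return labels


def off_boundary_mask(points: np.ndarray, margin: float = 0.5) -> np.ndarray:
    """True where a point is at least ``margin`` away from every zone boundary."""
    polys = clarke_polygons()
    boundary = shapely.union_all([g.boundary for g in polys.values()])
    pts = shapely.points(points)
    return shapely.distance(pts, boundary) > margin
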