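"""Independent brute-force oracles used to check the package's measures.

Deliberately naive: explicit point-to-segment arithmetic, point-sampled
length clipping, weighted medians by integer expansion, O(n^2) pair
enumeration for tau, explicit contingency tables for kappa.  Nothing here
calls the implementation paths under test.
"""

from __future__ import annotations

import math

import numpy as np
import shapely


def point_segment_distance(px, py, ax, ay, bx, by):
    """Euclidean distance from point (px,py) to segment (a,b)."""
    vx, vy = bx - ax, by - ay
    wx, wy = px - ax, py - ay
    c2 = vx * vx + vy * vy
    t = 0.0 if c2 == 0 else max(0.0, min(1.0, (vx * wx + vy * wy) / c2))
    return math.hypot(px - (ax + t * vx), py - (ay + t * vy))


def point_polyline_distance(px, py, coords):
    return min(
        point_segment_distance(px, py, coords[i][0], coords[i][1],
                               coords[i + 1][0], coords[i + 1][1])
        for i in range(len(coords) - 1)
    )


def brute_ej_screen(roads, unit, params):
    """Sum AADT / max(d, floor) over arterial segments within the radius."""
    cx, cy = unit.geometry.centroid.x, unit.geometry.centroid.y
    total, hit = 0.0, False
    for r in roads:
        if r.road_class not in params.arterial_classes:
            continue
        d = point_polyline_distance(cx, cy, list(r.geometry.coords))
        if d <= params.ej_radius:
            total += r.aadt / max(d, params.min_distance_floor)
            hit = True
    return total if hit else params.zero_exposure_value


def sampled_clipped_length(line, polygon, n=20000):
    """Length of line inside polygon, by midpoint sampling along the line."""
    length = line.length
    if length == 0:
        return 0.0
    s = (np.arange(n) + 0.5) / n * length
    pts = shapely.line_interpolate_point(line, s)
    inside = shapely.contains_xy(polygon, shapely.get_x(pts), shapely.get_y(pts))
    return float(inside.mean() * length)


def rect_clipped_length(coords, bounds):
    """Length of a polyline inside an axis-aligned rectangle, via
    Liang-Barsky parametric clipping of each sub-segment (exact)."""
    xmin, ymin, xmax, ymax = bounds
    total = 0.0
    for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
        dx, dy = x1 - x0, y1 - y0
        t0, t1 = 0.0, 1.0
        ok = True
        for p, q in ((-dx, x0 - xmin), (dx, xmax - x0),
                     (-dy, y0 - ymin), (dy, ymax - y0)):
            if p == 0:
                if q < 0:
                    ok = False
                    break
                continue
            t = q / p
            if p < 0:
                t0 = max(t0, t)
            else:
                t1 = min(t1, t)
        if ok and t1 > t0:
            total += (t1 - t0) * math.hypot(dx, dy)
    return total


def brute_aadt_density(roads, unit, n=None):
    """Density oracle for rectangular units: exact Liang-Barsky clipping
    (or point sampling when ``n`` is given)."""
    area = unit.geometry.area
    if n is not None:
        return sum(
            r.aadt * sampled_clipped_length(r.geometry, unit.geometry, n)
            for r in roads
        ) / area
    bounds = unit.geometry.bounds
    return sum(
        r.aadt * rect_clipped_length(list(r.geometry.coords), bounds)
        for r in roads
    ) / area


def expanded_weighted_median(values, weights):
    """Weighted median by explicit expansion; weights must be integers."""
    expanded = np.repeat(np.asarray(values, dtype=float),
                         np.asarray(weights, dtype=int))
    if expanded.size == 0:
        expanded = np.asarray(values, dtype=float)  # all-zero weights: unweighted
    expanded.sort()
    # smallest value whose cumulative count reaches half the total
    return float(expanded[math.ceil(expanded.size / 2) - 1])


def brute_parcel_proximity(roads, parcels, unit, params):
    scores, weights = [], []
    for p in parcels:
        if not p.is_residential or not unit.geometry.contains(p.location):
            continue
        truck = []
        for r in roads:
            if r.road_class not in params.arterial_classes:
                continue
            d = point_polyline_distance(p.location.x, p.location.y,
                                        list(r.geometry.coords))
            if d <= params.parcel_radius:
                truck.append(r.truck_aadt)
        if not truck:
            score = 0.0
        elif params.parcel_segment_reducer == "sum":
            score = float(sum(truck))
        else:
            score = float(np.median(truck))
        scores.append(score)
        weights.append(p.household_size
                       if params.parcel_weighting == "household_size" else 1)
    if not scores:
        return params.zero_exposure_value
    return expanded_weighted_median(scores, weights)


def brute_deciles(values):
    """Average ranks by explicit counting, then ceiling into 10 bins."""
    values = list(values)
    n = len(values)
    out = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        rank = less + (equal + 1) / 2.0
        out.append(math.ceil(10.0 * rank / n))
    return np.array(out, dtype=int)


def brute_good_agreement(a, b):
    return sum(1 for x, y in zip(a, b) if abs(x - y) <= 1) / len(a)


def brute_kappa(a, b):
    """Cohen's kappa from an explicit contingency table over deciles 1..10."""
    n = len(a)
    table = np.zeros((10, 10))
    for x, y in zip(a, b):
        table[int(x) - 1, int(y) - 1] += 1
    table /= n
    p_o = float(np.trace(table))
    p_e = float(table.sum(axis=1) @ table.sum(axis=0))
    if p_e >= 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def brute_tau_b(a, b):
    """Kendall's tau-b by O(n^2) enumeration of all pairs."""
    n = len(a)
    concordant = discordant = ties_a = ties_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            da, db = a[i] - a[j], b[i] - b[j]
            if da == 0 and db == 0:
                continue
            elif da == 0:
                ties_a += 1
            elif db == 0:
                ties_b += 1
            elif (da > 0) == (db > 0):
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    ta = sum(_tie_term(a))
    tb = sum(_tie_term(b))
    denom = math.sqrt((n0 - ta) * (n0 - tb))
    if denom == 0:
        return float("nan")
    return (concordant - discordant) / denom


def _tie_term(v):
    from collections import Counter

    return [c * (c - 1) / 2 for c in Counter(list(v)).values()]
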