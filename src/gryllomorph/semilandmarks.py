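"""Equidistant semilandmarks along digitized outlines.

An outline traced in a digitizer is an arbitrary-length polyline; shape
analysis needs every specimen represented by the same fixed number k of
corresponding points.  Correspondence for outlines without discrete anatomy
is established geometrically: k points spaced at equal arc-length intervals
("resampled by length"), starting from a vertex the digitizer placed at a
homologous position (for pronota, conventionally the anterior midline).

Semilandmarks are treated as fixed landmarks afterwards — no sliding.
"""

from __future__ import annotations

import numpy as np

from .tps_io import Configuration, Polyline

__all__ = [
    "arc_length",
    "signed_area",
    "normalize_traversal",
    "resample_equidistant",
]


def _path_vertices(curve: Polyline) -> np.ndarray:
    """Vertex array with the closing vertex appended for closed curves."""
    v = curve.vertices
    return np.vstack([v, v[:1]]) if curve.closed else v


def arc_length(curve: Polyline) -> float:
    """Total length of the polyline, including the closing segment if closed."""
    p = _path_vertices(curve)
    return float(np.hypot(*np.diff(p, axis=0).T).sum())


def signed_area(curve: Polyline) -> float:
    """Shoelace signed area of a closed polyline (positive = counter-clockwise)."""
    if not curve.closed:
        raise ValueError("signed area is defined for closed polylines only")
    x, y = curve.vertices.T
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def normalize_traversal(curve: Polyline) -> Polyline:
    """Return a copy of a closed polyline traversed counter-clockwise.

    The start vertex is preserved; a clockwise curve is reversed in place of
    traversal order.  A degenerate curve with zero signed area is rejected.
    """
    area = signed_area(curve)
    if area == 0.0:
        raise ValueError("polyline has zero signed area; orientation undefined")
    if area > 0:
        return Polyline(curve.vertices.copy(), closed=True)
    v = curve.vertices
    rev = np.vstack([v[:1], v[1:][::-1]])
    return Polyline(rev, closed=True)


def resample_equidistant(
    curve: Polyline, k: int, start_vertex_index: int = 0
) -> Configuration:
    """Resample a polyline into k points equally spaced in arc length.

    For a closed curve the points sit at arc-length positions i*L/k
    (i = 0..k-1) measured from ``start_vertex_index`` along the stored vertex
    order — no duplicated end point.  For an open curve they sit at
    i*L/(k-1), so both endpoints are retained.  Every output point lies
    exactly on the polyline (linear interpolation within segments).
    """
    if k < 3:
        raise ValueError("k must be at least 3")
    n = len(curve)
    if curve.closed:
        if not 0 <= start_vertex_index < n:
            raise ValueError(f"start_vertex_index {start_vertex_index} out of range")
        v = np.roll(curve.vertices, -start_vertex_index, axis=0)
        path = np.vstack([v, v[:1]])
    else:
        if start_vertex_index != 0:
            raise ValueError("open curves must be resampled from their first vertex")
        path = curve.vertices
    seg = np.hypot(*np.diff(path, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0.0:
        raise ValueError("degenerate zero-length curve")
    if curve.closed:
        targets = np.arange(k) * (total / k)
    else:
        targets = np.arange(k) * (total / (k - 1))
    x = np.interp(targets, s, path[:, 0])
    y = np.interp(targets, s, path[:, 1])
    return Configuration(np.column_stack([x, y]))
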