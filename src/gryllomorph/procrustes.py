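"""Generalized Procrustes superimposition and tangent-space diagnostics.

Configurations are compared after removing translation (centering), size
(centroid-size normalization to the unit preshape sphere) and rotation
(orthogonal least squares).  The generalized (GLS) procedure iterates
rotation-to-consensus and consensus re-estimation until the consensus stops
moving.  Reflections are excluded by default (rotation determinant +1), as is
usual for dorsal-view material; pass ``allow_reflection=True`` for mirrored
figures.

Distances: the *partial Procrustes distance* d is the root-sum-of-squares
between corresponding landmarks of two optimally superimposed unit-size
configurations (0 <= d <= 2); the *geodesic distance* rho = 2*arcsin(d/2) is
the corresponding great-circle arc on the preshape sphere, in radians.  The
tangent-space test regresses the Euclidean norm Y of each specimen's tangent
projection onto its rho; an uncentred correlation near 1 certifies that
variation is small enough for linear statistics in the tangent plane (the
tps-SMALL diagnostic).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .tps_io import Configuration

__all__ = [
    "centroid_size",
    "preshape",
    "align_pair",
    "partial_procrustes_distance",
    "geodesic_distance",
    "gpa",
    "AlignedSet",
    "tangent_project",
    "tangent_space_test",
    "TangentTestResult",
    "cyclic_align",
]

GPA_TOL = 1e-10
GPA_MAX_ITER = 100


def _points(config: Configuration | np.ndarray) -> np.ndarray:
    if isinstance(config, Configuration):
        return config.points
    return np.asarray(config, dtype=float)


def centroid_size(config: Configuration | np.ndarray) -> float:
    """Square root of summed squared distances of landmarks from their centroid."""
    p = _points(config)
    c = p - p.mean(axis=0)
    s = float(np.sqrt(np.sum(c * c)))
    if s == 0.0:
        raise ValueError("all landmarks coincide; centroid size is zero")
    return s


def preshape(config: Configuration | np.ndarray) -> np.ndarray:
    """Center and scale to unit centroid size (the preshape representation)."""
    p = _points(config)
    c = p - p.mean(axis=0)
    return c / centroid_size(p)


def _optimal_rotation(moving_pre: np.ndarray, target_pre: np.ndarray,
                      allow_reflection: bool) -> np.ndarray:
    # maximize tr(R^T H) with H = Y^T X over orthogonal R (det +1 unless allowed)
    h = moving_pre.T @ target_pre
    u, _, vt = np.linalg.svd(h)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        d = np.ones(len(u))
        d[-1] = -1.0
        r = (u * d) @ vt
    return r


def align_pair(
    moving: Configuration | np.ndarray,
    target: Configuration | np.ndarray,
    allow_reflection: bool = False,
) -> tuple[np.ndarray, float]:
    """Optimal superimposition of ``moving`` onto ``target``.

    Both inputs are centered and scaled to unit centroid size internally.
    Returns the 2x2 orthogonal matrix R minimizing ||X - Y R||_F (applied as
    ``preshape(moving) @ R``) and the minimized partial Procrustes distance.
    """
    y = preshape(moving)
    x = preshape(target)
    if y.shape != x.shape:
        raise ValueError(
            f"landmark count mismatch: {y.shape[0]} vs {x.shape[0]}"
        )
    r = _optimal_rotation(y, x, allow_reflection)
    d = float(np.linalg.norm(x - y @ r))
    return r, d


def partial_procrustes_distance(
    a: Configuration | np.ndarray,
    b: Configuration | np.ndarray,
    allow_reflection: bool = False,
) -> float:
    return align_pair(a, b, allow_reflection)[1]


def geodesic_distance(partial_d: float) -> float:
    """Great-circle (Procrustes) distance in radians: rho = 2*arcsin(d/2)."""
    if not -1e-12 <= partial_d <= 2 + 1e-12:
        raise ValueError(f"partial Procrustes distance {partial_d} outside [0, 2]")
    return float(2.0 * np.arcsin(np.clip(partial_d / 2.0, 0.0, 1.0)))


@dataclasses.dataclass
class AlignedSet:
    """Output of generalized Procrustes superimposition.

    ``aligned`` configurations are centered, unit-centroid-size and rotated
    to the consensus; ``centroid_sizes`` are the pre-normalization sizes.
    """

    aligned: list[Configuration]
    consensus: Configuration
    centroid_sizes: np.ndarray
    iterations: int
    converged: bool

    def __len__(self) -> int:
        return len(self.aligned)

    @property
    def ids(self) -> list[str]:
        return [c.specimen_id for c in self.aligned]


def gpa(
    configs: Sequence[Configuration],
    tol: float = GPA_TOL,
    max_iter: int = GPA_MAX_ITER,
    allow_reflection: bool = False,
) -> AlignedSet:
    """Generalized (GLS) Procrustes superimposition.

    All configurations are centered and normalized to unit centroid size; the
    first seeds the consensus; each iteration rotates every configuration to
    the consensus and re-estimates it as the renormalized arithmetic mean,
    until the consensus moves by less than ``tol`` (partial Procrustes
    distance between successive consensuses) or ``max_iter`` is reached.
    """
    if len(configs) == 0:
        raise ValueError("gpa needs at least one configuration")
    k = configs[0].k
    for c in configs:
        if c.k != k:
            raise ValueError("landmark count mismatch across configurations")
    sizes = np.array([centroid_size(c) for c in configs])
    pre = [preshape(c) for c in configs]

    consensus = pre[0].copy()
    converged = False
    iterations = 0
    rotated = pre
    for iterations in range(1, max_iter + 1):
        rotated = [
            y @ _optimal_rotation(y, consensus, allow_reflection) for y in pre
        ]
        mean = np.mean(rotated, axis=0)
        mean -= mean.mean(axis=0)
        new_consensus = mean / centroid_size(mean)
        move = partial_procrustes_distance(new_consensus, consensus, allow_reflection)
        consensus = new_consensus
        if move < tol:
            converged = True
            break
    # final pass so every aligned configuration matches the final consensus
    rotated = [y @ _optimal_rotation(y, consensus, allow_reflection) for y in pre]

    aligned = [
        Configuration(pts, specimen_id=c.specimen_id)
        for pts, c in zip(rotated, configs)
    ]
    return AlignedSet(
        aligned=aligned,
        consensus=Configuration(consensus, specimen_id="consensus"),
        centroid_sizes=sizes,
        iterations=iterations,
        converged=converged,
    )


def tangent_project(aligned_set: AlignedSet) -> list[np.ndarray]:
    """Orthogonal projection of each aligned preshape onto the tangent plane.

    With z the consensus unit vector, each aligned configuration x maps to
    x - z*(z . x); the consensus itself projects to the zero vector.  Returns
    plain (k, 2) arrays (a tangent vector may be identically zero, which a
    Configuration cannot represent).
    """
    z = aligned_set.consensus.points.ravel()
    z = z / np.linalg.norm(z)
    out = []
    for c in aligned_set.aligned:
        x = c.points.ravel()
        xt = x - z * (z @ x)
        out.append(xt.reshape(-1, 2))
    return out


@dataclasses.dataclass
class TangentTestResult:
    """Per-specimen geodesic (rho) and tangent (Y) distances to the consensus.

    ``uncentred_correlation`` = sum(rho*Y)/sqrt(sum(rho^2)*sum(Y^2)) and
    ``slope_through_origin`` = sum(rho*Y)/sum(rho^2) are the primary
    diagnostics; an ordinary free-intercept regression is reported alongside.
    """

    geodesic_distances: np.ndarray
    tangent_distances: np.ndarray
    uncentred_correlation: float
    slope_through_origin: float
    ols_slope: float
    ols_intercept: float


def tangent_space_test(aligned_set: AlignedSet) -> TangentTestResult:
    """tps-SMALL analogue: is shape variation small enough for tangent-space statistics?"""
    if len(aligned_set) < 3:
        raise ValueError("tangent-space test needs at least 3 specimens")
    z = aligned_set.consensus.points
    d = np.array([np.linalg.norm(c.points - z) for c in aligned_set.aligned])
    if np.all(d < 1e-14):
        raise ValueError("all specimens identical to consensus; diagnostic undefined")
    rho = np.array([geodesic_distance(di) for di in d])
    tangents = tangent_project(aligned_set)
    y = np.array([np.linalg.norm(t) for t in tangents])
    sxy = float(rho @ y)
    sxx = float(rho @ rho)
    syy = float(y @ y)
    corr = sxy / np.sqrt(sxx * syy)
    slope0 = sxy / sxx
    b1, b0 = np.polyfit(rho, y, 1)
    return TangentTestResult(
        geodesic_distances=rho,
        tangent_distances=y,
        uncentred_correlation=corr,
        slope_through_origin=slope0,
        ols_slope=float(b1),
        ols_intercept=float(b0),
    )


def cyclic_align(
    config: Configuration,
    reference: Configuration,
    allow_reflection: bool = False,
) -> tuple[Configuration, int]:
    """Best cyclic relabelling of closed-outline semilandmarks against a reference.

    Tries every cyclic shift of the point order and keeps the one minimizing
    the partial Procrustes distance to ``reference``.  Used when digitized
    start points cannot be trusted to be homologous.
    """
    best_shift, best_d = 0, np.inf
    for s in range(config.k):
        d = partial_procrustes_distance(
            np.roll(config.points, -s, axis=0), reference, allow_reflection
        )
        if d < best_d:
            best_shift, best_d = s, d
    return (
        Configuration(np.roll(config.points, -best_shift, axis=0), config.specimen_id),
        best_shift,
    )
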