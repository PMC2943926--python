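"""Genus consensus shapes, thin-plate splines, relative warps, and ordination.

The thin-plate spline (TPS) is the smoothest interpolating map taking one
landmark configuration onto another; its bending energy measures non-affine
shape change.  With kernel U(r) = r^2 log r^2 and reference landmarks as
knots, the bordered system

    L = [[K, Q], [Q^T, 0]],   K_ij = U(|p_i - p_j|),   Q = [1 | x | y]

yields the bending-energy matrix (upper-left k x k block of L^-1), whose
eigenvectors are the principal warps; exactly three zero eigenvalues span
the affine subspace.

Relative warps are the principal components of shape variation: the
specimens x shape-variables weight matrix is column-centered and decomposed
by SVD.  With alpha = 0 (the default) the weight matrix holds raw tangent
residuals — uniform and non-uniform variation together — and the analysis
coincides with ordinary shape PCA; alpha != 0 re-weights partial-warp scores
by (bending-energy eigenvalue)^(-alpha/2), emphasising large-scale
(alpha > 0) or small-scale (alpha < 0) deformation, and drops the affine
component.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .procrustes import AlignedSet, gpa
from .tps_io import Configuration

__all__ = [
    "genus_consensus",
    "BendingEnergyModel",
    "bending_energy",
    "tps_warp",
    "RelativeWarpResult",
    "relative_warps",
    "quadrant_of",
    "OrdinationResult",
    "pcoa",
]


def genus_consensus(
    groups: Mapping[str, Sequence[Configuration]]
) -> dict[str, Configuration]:
    """Per-genus GLS consensus configurations.

    Each genus's members are superimposed by their own generalized Procrustes
    fit and that fit's consensus is returned; a monotypic genus yields its
    single normalized configuration.
    """
    out: dict[str, Configuration] = {}
    for genus, members in groups.items():
        if len(members) == 0:
            raise ValueError(f"genus {genus!r} has no members")
        fit = gpa(list(members))
        out[genus] = Configuration(fit.consensus.points, specimen_id=genus)
    return out


# ---------------------------------------------------------------------------
# thin-plate splines
# ---------------------------------------------------------------------------

def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r^2, with U(0) = 0
    logr2 = np.zeros_like(r2)
    np.log(r2, out=logr2, where=r2 > 0.0)
    return r2 * logr2


def _bordered_system(reference: np.ndarray) -> np.ndarray:
    k = reference.shape[0]
    r2 = cdist(reference, reference, "sqeuclidean")
    if np.any(r2[~np.eye(k, dtype=bool)] == 0.0):
        raise ValueError("coincident landmarks make the spline system singular")
    kmat = _tps_kernel(r2)
    q = np.column_stack([np.ones(k), reference])
    top = np.hstack([kmat, q])
    bottom = np.hstack([q.T, np.zeros((3, 3))])
    return np.vstack([top, bottom])


@dataclasses.dataclass
class BendingEnergyModel:
    """Bending-energy matrix and principal warps of a reference configuration."""

    reference: Configuration
    energy_matrix: np.ndarray  # k x k symmetric PSD
    principal_warps: np.ndarray  # columns = eigenvectors, sorted by eigenvalue desc
    eigenvalues: np.ndarray  # nonnegative, descending


def bending_energy(reference: Configuration) -> BendingEnergyModel:
    """Bending-energy matrix of a reference: upper-left block of the inverse bordered system."""
    p = reference.points
    lmat = _bordered_system(p)
    linv = np.linalg.inv(lmat)
    k = p.shape[0]
    e = linv[:k, :k]
    e = 0.5 * (e + e.T)
    w, v = np.linalg.eigh(e)
    order = np.argsort(w)[::-1]
    return BendingEnergyModel(
        reference=reference,
        energy_matrix=e,
        principal_warps=v[:, order],
        eigenvalues=w[order],
    )


def tps_warp(
    source: Configuration,
    target: Configuration,
    points: np.ndarray | Sequence[tuple[float, float]],
) -> np.ndarray:
    """Map query points through the thin-plate spline taking source landmarks to target.

    The fitted pair of interpolants (one per coordinate) reproduces each
    target landmark exactly; arbitrary query points pass through the spline,
    which supports deformation-grid rendering.
    """
    if source.k != target.k:
        raise ValueError("source and target must have equal landmark counts")
    src = source.points
    lmat = _bordered_system(src)
    rhs = np.vstack([target.points, np.zeros((3, 2))])
    sol = np.linalg.solve(lmat, rhs)
    w, a = sol[: source.k], sol[source.k :]
    q = np.asarray(points, dtype=float).reshape(-1, 2)
    u = _tps_kernel(cdist(q, src, "sqeuclidean"))
    return a[0] + q @ a[1:] + u @ w


def deformation_grid(
    source: Configuration,
    target: Configuration,
    n_lines: int = 20,
    magnification: float = 1.0,
    pad: float = 0.1,
) -> np.ndarray:
    """Regular grid over the source, warped toward the target; for plotting.

    Returns an (n_lines*n_lines, 2) array of warped grid nodes.  The shape
    difference is scaled by ``magnification`` before warping.
    """
    tgt = Configuration(
        source.points + magnification * (target.points - source.points),
        target.specimen_id,
    )
    lo = source.points.min(axis=0)
    hi = source.points.max(axis=0)
    span = hi - lo
    lo, hi = lo - pad * span, hi + pad * span
    gx, gy = np.meshgrid(
        np.linspace(lo[0], hi[0], n_lines), np.linspace(lo[1], hi[1], n_lines)
    )
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    return tps_warp(source, tgt, grid)


# ---------------------------------------------------------------------------
# relative warps
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RelativeWarpResult:
    """SVD decomposition of the (column-centered) weight matrix."""

    alpha: float
    labels: list[str]
    weight_matrix: np.ndarray  # n x m, column-centered
    singular_values: np.ndarray  # descending
    percent_variance: np.ndarray  # sums to 100
    scores: np.ndarray  # n x r specimen scores
    warp_vectors: np.ndarray  # r x m right singular vectors


def relative_warps(aligned: AlignedSet, alpha: float = 0.0) -> RelativeWarpResult:
    """Relative warps of an aligned set: SVD of the weight matrix.

    alpha = 0: the weight matrix is the raw tangent residuals from the
    consensus (uniform + non-uniform variation together; equivalent to shape
    PCA).  alpha != 0: partial-warp scores re-weighted by
    eigenvalue^(-alpha/2), affine component excluded.
    """
    n = len(aligned)
    if n < 3:
        raise ValueError("relative warps need at least 3 configurations")
    z = aligned.consensus.points.ravel()
    z = z / np.linalg.norm(z)
    resid = np.array(
        [c.points.ravel() - z * (z @ c.points.ravel()) for c in aligned.aligned]
    )
    if alpha == 0.0:
        weight = resid
    else:
        bem = bending_energy(aligned.consensus)
        nz = bem.eigenvalues > 1e-8 * bem.eigenvalues[0]
        warps_basis = bem.principal_warps[:, nz]  # k x (k-3)
        lam = bem.eigenvalues[nz]
        rx = resid[:, 0::2] @ warps_basis  # n x (k-3)
        ry = resid[:, 1::2] @ warps_basis
        scale = lam ** (-alpha / 2.0)
        weight = np.empty((n, 2 * warps_basis.shape[1]))
        weight[:, 0::2] = rx * scale
        weight[:, 1::2] = ry * scale

    weight = weight - weight.mean(axis=0)
    u, s, vt = np.linalg.svd(weight, full_matrices=False)
    tot = float(np.sum(s**2))
    if tot == 0.0:
        raise ValueError("no shape variation in the aligned set")
    r = int(np.sum(s > 1e-12 * s[0]))
    u, s_r, vt = u[:, :r], s[:r], vt[:r]
    # sign convention: largest-|loading| entry of each warp vector made positive
    for j in range(r):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    percent = 100.0 * s_r**2 / tot
    return RelativeWarpResult(
        alpha=alpha,
        labels=aligned.ids,
        weight_matrix=weight,
        singular_values=s_r,
        percent_variance=percent,
        scores=u * s_r,
        warp_vectors=vt,
    )


def quadrant_of(score2d: tuple[float, float]) -> str:
    """Sign-based quadrant of an (RW1, RW2) pair; exact zeros map to 'axis'."""
    x, y = score2d
    if x == 0.0 or y == 0.0:
        return "axis"
    if x > 0:
        return "I" if y > 0 else "IV"
    return "II" if y > 0 else "III"


# ---------------------------------------------------------------------------
# principal-coordinates ordination
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class OrdinationResult:
    """Metric ordination (PCoA) of a distance matrix."""

    labels: list[str]
    axis_scores: np.ndarray  # n x n_axes, columns centered
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)


def pcoa(distmat, n_axes: int = 3) -> OrdinationResult:
    """Principal-coordinates analysis of a distance matrix.

    The doubly centered -D^2/2 matrix is eigendecomposed; axis scores are
    eigenvectors scaled by the square root of their (positive) eigenvalues.
    Negative eigenvalues are reported but their axes dropped; if fewer
    positive axes exist than requested, the result is truncated with a
    warning.
    """
    n = len(distmat.labels)
    if not 1 <= n_axes <= n - 1:
        raise ValueError(f"n_axes must be in [1, {n - 1}]")
    from skbio import DistanceMatrix as _SkbioDM
    from skbio.stats.ordination import pcoa as _skbio_pcoa

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(_SkbioDM(distmat.d, ids=list(distmat.labels)), method="eigh")
    eigvals = np.sort(np.asarray(res.eigvals, dtype=float))[::-1]
    n_pos = int(np.sum(eigvals > 1e-12 * max(abs(eigvals[0]), 1e-300)))
    if n_pos == 0:  # all-zero distances: every score is zero
        return OrdinationResult(
            labels=list(distmat.labels),
            axis_scores=np.zeros((n, n_axes)),
            eigenvalues=eigvals,
        )
    if n_pos < n_axes:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {n_pos} axes "
            f"instead of {n_axes}",
            stacklevel=2,
        )
    take = min(n_axes, n_pos)
    scores = np.asarray(res.samples, dtype=float)[:, :take]
    scores = scores - scores.mean(axis=0)
    return OrdinationResult(
        labels=list(distmat.labels), axis_scores=scores, eigenvalues=eigvals
    )
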