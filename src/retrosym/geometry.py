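"""Shape-geometry primitives.

Reflection, Procrustes superimposition and distance, generalized Procrustes
analysis (GPA), symmetry-plane estimation, and equal-arc-length resampling of
semilandmark curves.

Conventions
-----------
* Configurations are centred and scaled to unit centroid size before any
  distance is computed; the Procrustes distance reported everywhere is the
  square root of the minimised residual sum of squares between such
  unit-size, centred configurations (with an optimal relative scale also
  fitted, so ``d = sqrt(1 - T^2)`` where ``T`` is the Procrustes correlation).
* Reflection is disallowed during distance computation; it is available as an
  explicit option of :func:`optimal_superimposition` for aligning mirrored
  copies.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .containers import (
    BilateralPairing,
    GPAResult,
    LandmarkConfiguration,
    Plane,
    SuperimpositionResult,
)

__all__ = [
    "reflect_across_plane",
    "center_and_scale",
    "centroid_size",
    "optimal_superimposition",
    "procrustes_distance",
    "GeneralizedProcrustes",
    "generalized_procrustes",
    "fit_midline_plane",
    "midline_plane_objective",
    "resample_polyline",
    "rotation_between_vectors",
    "canonical_frame",
]


# ---------------------------------------------------------------------------
# elementary transforms


def reflect_across_plane(points: np.ndarray, plane: Plane) -> np.ndarray:
    """Mirror ``points`` across ``plane``.

    An isometry: all inter-point distances are preserved.
    """
    pts = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("reflect_across_plane: non-finite input coordinates")
    d = pts @ plane.normal - plane.offset
    return pts - 2.0 * np.outer(d, plane.normal)


def centroid_size(coords: np.ndarray) -> float:
    """Root summed squared distance of points to their centroid."""
    c = np.asarray(coords, float)
    return float(np.linalg.norm(c - c.mean(axis=0)))


def center_and_scale(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Centre the present landmarks at the origin and scale to centroid size 1."""
    pres = config.present_mask
    if pres.sum() < 1:
        raise ValueError("center_and_scale: no present landmarks")
    coords = config.coords.copy()
    mu = coords[pres].mean(axis=0)
    coords[pres] -= mu
    cs = np.linalg.norm(coords[pres])
    if cs <= 0:
        raise ValueError("center_and_scale: zero centroid size (coincident points)")
    coords[pres] /= cs
    return config.with_coords(coords)


def rotation_between_vectors(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix R (row convention: v @ R) mapping unit a onto unit b."""
    a = np.asarray(a, float) / np.linalg.norm(a)
    b = np.asarray(b, float) / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-15 and c > 0:
        return np.eye(3)
    if c < -1.0 + 1e-9:
        # antiparallel: rotate 180 deg about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    R_col = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    return R_col.T  # row-vector convention


def canonical_frame(plane: Plane) -> tuple[np.ndarray, np.ndarray]:
    """Rigid map sending ``plane`` to the plane x = 0.

    Returns ``(R, p0)`` such that ``y = (x - p0) @ R`` places the plane at
    x = 0 with the plane normal mapped onto +x̂.  Inverse: ``x = y @ R.T + p0``.
    """
    R = rotation_between_vectors(plane.normal, np.array([1.0, 0.0, 0.0]))
    p0 = plane.offset * plane.normal
    return R, p0


# ---------------------------------------------------------------------------
# superimposition and Procrustes distance


def _shared_present(a: LandmarkConfiguration, b: LandmarkConfiguration) -> np.ndarray:
    if a.labels != b.labels:
        raise ValueError("optimal_superimposition: label sets/order differ")
    return a.present_mask & b.present_mask


def optimal_superimposition(
    target: LandmarkConfiguration,
    moving: LandmarkConfiguration,
    allow_reflection: bool = False,
    with_scaling: bool = True,
) -> SuperimpositionResult:
    """Least-squares similarity fit of ``moving`` onto ``target``.

    The rotation is obtained from the SVD of the cross-covariance (Kabsch /
    orthogonal Procrustes); an improper (det = −1) orthogonal matrix is used
    only when ``allow_reflection`` and it lowers the residual.  ``distance``
    is evaluated on centred unit-centroid-size copies of both configurations
    and is independent of the input position, orientation and scale.
    """
    shared = _shared_present(target, moving)
    if shared.sum() < 3:
        raise ValueError("optimal_superimposition: fewer than 3 shared landmarks")
    X = target.coords[shared]
    Y = moving.coords[shared]
    muX, muY = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - muX, Y - muY
    nx, ny = np.linalg.norm(Xc), np.linalg.norm(Yc)
    if nx <= 0 or ny <= 0:
        raise ValueError("optimal_superimposition: degenerate (coincident) points")
    if (np.linalg.matrix_rank(Xc, tol=1e-12 * nx) < 2
            or np.linalg.matrix_rank(Yc, tol=1e-12 * ny) < 2):
        raise ValueError("optimal_superimposition: collinear landmark set")

    H = Yc.T @ Xc
    U, S, Vt = np.linalg.svd(H)
    det_uv = np.linalg.det(U) * np.linalg.det(Vt)
    flip = np.ones(3)
    if det_uv < 0 and not allow_reflection:
        flip[-1] = -1.0  # force a proper rotation; drop the smallest mode
    R = (U * flip) @ Vt
    trace = float(np.sum(S * flip))
    used_reflection = bool(np.linalg.det(R) < 0)

    # distance on unit-size, centred copies, as an explicit residual norm
    # (numerically exact at zero, unlike sqrt(1 - T^2))
    T = trace / (nx * ny)  # Procrustes correlation, |T| <= 1
    beta = max(T, 0.0) if with_scaling else 1.0
    distance = float(np.linalg.norm(Xc / nx - beta * (Yc / ny) @ R))

    scale = trace / (ny * ny) if with_scaling else 1.0
    translation = muX - scale * muY @ R
    return SuperimpositionResult(
        rotation=R, scale=float(scale), translation=translation,
        distance=distance, used_reflection=used_reflection)


def procrustes_distance(a: LandmarkConfiguration, b: LandmarkConfiguration) -> float:
    """Procrustes distance between two configurations.

    Root of the minimised residual sum of squares after translation, scaling
    and (proper) rotation of unit-centroid-size configurations.  Symmetric in
    its arguments and invariant to similarity transforms of either.
    """
    return optimal_superimposition(a, b, allow_reflection=False,
                                   with_scaling=True).distance


# ---------------------------------------------------------------------------
# generalized Procrustes analysis


class GeneralizedProcrustes(BaseEstimator):
    """Iterative superimposition of many configurations onto their mean.

    Parameters
    ----------
    tol : float, default 1e-10
        Convergence threshold on the displacement of the (unit-size) mean
        shape between iterations.
    max_iter : int, default 100
        Iteration cap; non-convergence is reported via ``converged_``, not
        raised.
    with_scaling : bool, default True
        Fit an optimal scale when aligning each sample to the mean.

    Attributes
    ----------
    mean_shape_ : LandmarkConfiguration
        Consensus shape, unit centroid size, centred at the origin.
    aligned_ : list of LandmarkConfiguration
        Input samples superimposed on ``mean_shape_``.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 100,
                 with_scaling: bool = True):
        self.tol = tol
        self.max_iter = max_iter
        self.with_scaling = with_scaling

    def fit(self, samples: list[LandmarkConfiguration]) -> "GeneralizedProcrustes":
        if len(samples) < 2:
            raise ValueError("GPA requires at least 2 samples")
        labels = samples[0].labels
        for s in samples[1:]:
            if s.labels != labels:
                raise ValueError("GPA samples must share one label set")
        shared = np.logical_and.reduce([s.present_mask for s in samples])
        if shared.sum() < 4:
            raise ValueError("GPA requires >= 4 landmarks present in all samples")

        unit = [center_and_scale(
            LandmarkConfiguration(labels, s.coords, shared)) for s in samples]
        mean = unit[0]
        n_iter = 0
        converged = False
        for n_iter in range(1, self.max_iter + 1):
            aligned = [self._align(mean, s) for s in unit]
            stack = np.stack([a.coords[shared] for a in aligned])
            new_mean_coords = np.full_like(mean.coords, np.nan)
            new_mean_coords[shared] = stack.mean(axis=0)
            new_mean = center_and_scale(
                LandmarkConfiguration(labels, new_mean_coords, shared))
            delta = float(np.linalg.norm(
                new_mean.coords[shared] - mean.coords[shared]))
            mean = new_mean
            if delta < self.tol:
                converged = True
                break
        self.aligned_ = [self._align(mean, s) for s in unit]
        self.mean_shape_ = mean
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    @staticmethod
    def _align(mean: LandmarkConfiguration,
               sample: LandmarkConfiguration) -> LandmarkConfiguration:
        res = optimal_superimposition(mean, sample, allow_reflection=False)
        coords = np.full_like(sample.coords, np.nan)
        coords[sample.present_mask] = res.apply(sample.coords[sample.present_mask])
        return sample.with_coords(coords)

    def result_(self) -> GPAResult:
        return GPAResult(mean_shape=self.mean_shape_, aligned=self.aligned_,
                         iterations=self.n_iter_, converged=self.converged_)


def generalized_procrustes(samples: list[LandmarkConfiguration],
                           tol: float = 1e-10, max_iter: int = 100) -> GPAResult:
    """Functional wrapper over :class:`GeneralizedProcrustes`."""
    return GeneralizedProcrustes(tol=tol, max_iter=max_iter).fit(samples).result_()


# ---------------------------------------------------------------------------
# symmetry-plane estimation


def _plane_normal_matrix(config: LandmarkConfiguration, pairing: BilateralPairing
                         ) -> tuple[np.ndarray, np.ndarray, float]:
    """Assemble the quadratic form for the midline-plane objective.

    For a candidate unit normal n with optimal offset, the objective

        sum_pairs ||reflect(left) - right||^2 + sum_midline dist^2

    equals ``const + n' A n`` where A and the weighted centroid c are computed
    below (pair midpoints enter with weight 4, midline points with weight 1;
    the pair difference vectors contribute the negative-definite part).
    """
    li, ri, mi = pairing.indices(config)
    pres = config.present_mask
    keep = pres[li] & pres[ri]
    li, ri = li[keep], ri[keep]
    mi = mi[pres[mi]]
    L, R_ = config.coords[li], config.coords[ri]
    Mx = config.coords[mi]
    if len(li) < 2 and len(mi) < 3:
        raise ValueError("fit_midline_plane: need >= 2 pairs or >= 3 midline points")
    v = L - R_
    m = 0.5 * (L + R_)
    wsum = 4.0 * len(m) + len(Mx)
    c = (4.0 * m.sum(axis=0) + (Mx.sum(axis=0) if len(Mx) else 0.0)) / wsum
    A = -v.T @ v + 4.0 * (m - c).T @ (m - c)
    if len(Mx):
        A += (Mx - c).T @ (Mx - c)
    const = float(np.sum(v * v))
    return A, c, const


def midline_plane_objective(config: LandmarkConfiguration,
                            pairing: BilateralPairing, plane: Plane) -> float:
    """Symmetry objective of an explicit plane (used for verification)."""
    li, ri, mi = pairing.indices(config)
    pres = config.present_mask
    keep = pres[li] & pres[ri]
    L, R_ = config.coords[li[keep]], config.coords[ri[keep]]
    Mx = config.coords[mi[pres[mi]]]
    total = float(np.sum((reflect_across_plane(L, plane) - R_) ** 2))
    if len(Mx):
        total += float(np.sum(plane.signed_distance(Mx) ** 2))
    return total


def fit_midline_plane(config: LandmarkConfiguration,
                      pairing: BilateralPairing) -> Plane:
    """Best-fit symmetry plane of a bilateral configuration.

    Minimises the summed squared mismatch between each reflected left
    landmark and its right partner plus the squared distances of midline
    landmarks to the plane.  Solved in closed form as a 3×3 eigenproblem.
    The normal is oriented from the mean right side toward the mean left side.
    """
    A, c, _ = _plane_normal_matrix(config, pairing)
    evals, evecs = np.linalg.eigh(A)
    scale = max(1.0, float(np.abs(evals).max()))
    if evals[1] - evals[0] < 1e-10 * scale:
        raise ValueError("fit_midline_plane: degenerate geometry, plane not unique")
    n = evecs[:, 0]
    plane = Plane(n, float(n @ c))

    li, ri, mi = pairing.indices(config)
    pres = config.present_mask
    keep = pres[li] & pres[ri]
    if keep.any():
        L, R_ = config.coords[li[keep]], config.coords[ri[keep]]
        side = float((L.mean(axis=0) - R_.mean(axis=0)) @ plane.normal)
        if abs(side) < 1e-12:
            side = float(plane.signed_distance(L[:1])[0])
        if side < 0:
            plane = plane.flipped()
    elif plane.normal[np.argmax(np.abs(plane.normal))] < 0:
        plane = plane.flipped()
    return plane


# ---------------------------------------------------------------------------
# semilandmark curves


def resample_polyline(points: np.ndarray, k: int) -> np.ndarray:
    """Resample a piecewise-linear 3-D curve to ``k`` equally spaced points.

    Spacing is equal in arc length along the input polyline; the first and
    last input points are preserved exactly.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("resample_polyline: need an (m>=2, 3) point array")
    if k < 2:
        raise ValueError("resample_polyline: k must be >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("resample_polyline: zero-length polyline")
    t = np.linspace(0.0, s[-1], k)
    out = np.column_stack([np.interp(t, s, pts[:, j]) for j in range(pts.shape[1])])
    out[0], out[-1] = pts[0], pts[-1]
    return out
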