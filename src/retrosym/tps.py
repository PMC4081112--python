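"""Thin-plate-spline interpolation in 3-D.

Used to carry a surface mesh along with a landmark displacement (e.g. to warp
a scanned surface onto its symmetrized landmark configuration).  The kernel
is the 3-D biharmonic fundamental solution U(r) = r, so with zero
regularization the spline interpolates the landmark targets exactly and
reproduces any affine map with zero kernel energy.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import LandmarkConfiguration, Mesh

__all__ = ["ThinPlateSpline", "fit_tps", "apply_tps", "warp_mesh"]


class ThinPlateSpline(BaseEstimator, TransformerMixin):
    """3-D thin-plate spline x -> c + x A + sum_j w_j U(||x - c_j||).

    Parameters
    ----------
    regularization : float, default 0.0
        Ridge added to the kernel block.  Zero gives exact interpolation at
        the centers; a small positive value smooths near-degenerate center
        configurations.

    Attributes
    ----------
    centers_ : (m, 3) source landmarks.
    kernel_weights_ : (m, 3) kernel coefficients; each column sums to zero
        and is orthogonal to the center coordinates (the side conditions).
    affine_ : (3, 3) linear part (row convention), offset_ : (3,) translation.
    """

    def __init__(self, regularization: float = 0.0):
        self.regularization = regularization

    def fit(self, source: np.ndarray, target: np.ndarray) -> "ThinPlateSpline":
        S = np.asarray(source, float)
        T = np.asarray(target, float)
        if S.ndim != 2 or S.shape[1] != 3 or S.shape != T.shape:
            raise ValueError("source and target must be matching (m, 3) arrays")
        m = len(S)
        if m < 4:
            raise ValueError("TPS in 3-D needs at least 4 centers")
        if self.regularization == 0:
            centered = S - S.mean(axis=0)
            if (np.linalg.matrix_rank(centered,
                                      tol=1e-10 * np.linalg.norm(centered)) < 3
                    or len(np.unique(S.round(12), axis=0)) < m):
                raise np.linalg.LinAlgError(
                    "TPS system is singular (coplanar or duplicated centers); "
                    "try a positive regularization")
        K = cdist(S, S)
        P = np.column_stack([np.ones(m), S])
        A = np.zeros((m + 4, m + 4))
        A[:m, :m] = K + self.regularization * np.eye(m)
        A[:m, m:] = P
        A[m:, :m] = P.T
        b = np.vstack([T, np.zeros((4, 3))])
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "TPS system is singular (coplanar or duplicated centers); "
                "try a positive regularization") from err
        self.centers_ = S.copy()
        self.kernel_weights_ = sol[:m]
        self.offset_ = sol[m]
        self.affine_ = sol[m + 1:]
        return self

    def transform(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        if not np.all(np.isfinite(pts)):
            raise ValueError("TPS transform: non-finite input points")
        U = cdist(pts, self.centers_)
        return self.offset_ + pts @ self.affine_ + U @ self.kernel_weights_


def fit_tps(source: np.ndarray, target: np.ndarray,
            regularization: float = 0.0) -> ThinPlateSpline:
    """Fit a 3-D thin-plate spline mapping ``source`` landmarks to ``target``."""
    return ThinPlateSpline(regularization=regularization).fit(source, target)


def apply_tps(model: ThinPlateSpline, points: np.ndarray) -> np.ndarray:
    """Evaluate a fitted spline at arbitrary points."""
    return model.transform(points)


def warp_mesh(mesh: Mesh, source: LandmarkConfiguration,
              target: LandmarkConfiguration,
              regularization: float = 0.0) -> Mesh:
    """Warp mesh vertices by the TPS defined by a landmark displacement.

    ``source`` and ``target`` must share labels; only landmarks present in
    both are used as spline centers.  Faces are unchanged.
    """
    if source.labels != target.labels:
        raise ValueError("warp_mesh: source/target label sets differ")
    shared = source.present_mask & target.present_mask
    model = fit_tps(source.coords[shared], target.coords[shared], regularization)
    return Mesh(model.transform(mesh.vertices), mesh.faces.copy())
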