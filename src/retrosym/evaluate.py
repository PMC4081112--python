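"""Evaluation of retrodeformations.

Procrustes-distance scoring, percent improvement, pairwise distance
distributions, shape PCA on Procrustes-aligned coordinates, and convex-hull
membership in PC score space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .containers import GPAResult, LandmarkConfiguration
from .geometry import optimal_superimposition, procrustes_distance

__all__ = [
    "percent_improvement",
    "pairwise_distance_distribution",
    "ShapePCA",
    "PCAResult",
    "shape_pca",
    "hull_membership",
    "EvaluationReport",
    "evaluate_retrodeformation",
]


def percent_improvement(d_deformed: float, d_retro: float) -> float:
    """Percent closer in shape the retrodeformed model is to the original.

    ``100 * (d_deformed - d_retro) / d_deformed``; negative when
    retrodeformation moved the shape further away.  Full precision is
    returned; reports round to one decimal (half-even).
    """
    if d_deformed <= 0:
        raise ValueError("percent_improvement undefined for d_deformed <= 0")
    return 100.0 * (d_deformed - d_retro) / d_deformed


def pairwise_distance_distribution(samples: list[LandmarkConfiguration]
                                   ) -> list[float]:
    """All n(n-1)/2 pairwise Procrustes distances, lexicographic by index."""
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    return [procrustes_distance(samples[i], samples[j])
            for i in range(len(samples)) for j in range(i + 1, len(samples))]


# ---------------------------------------------------------------------------
# shape PCA


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    component_scores: np.ndarray
    loadings: np.ndarray
    variance_fractions: np.ndarray


class ShapePCA(BaseEstimator):
    """PCA of Procrustes-aligned landmark coordinates.

    Fitted from a :class:`GPAResult`; new specimens are projected by aligning
    them to the stored GPA mean and applying the stored loadings, without
    re-running the superimposition of the training sample.

    Attributes
    ----------
    eigenvalues_ : explained variances, descending.
    loadings_ : (components, 3n) principal axes; the largest-magnitude entry
        of each axis is made positive (deterministic sign convention).
    scores_ : (samples, components) training scores.
    variance_fractions_ : eigenvalues over total variance.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, gpa: GPAResult) -> "ShapePCA":
        aligned = gpa.aligned
        if len(aligned) < 3:
            raise ValueError("shape PCA requires at least 3 samples")
        self.mean_shape_ = gpa.mean_shape
        self.mask_ = gpa.mean_shape.present_mask.copy()
        X = np.stack([a.coords[self.mask_].ravel() for a in aligned])
        k = self.n_components or min(len(aligned) - 1, X.shape[1])
        pca = PCA(n_components=k, svd_solver="full")
        scores = pca.fit_transform(X)
        signs = np.sign(pca.components_[
            np.arange(k), np.argmax(np.abs(pca.components_), axis=1)])
        signs[signs == 0] = 1.0
        self.loadings_ = pca.components_ * signs[:, None]
        self.scores_ = scores * signs[None, :]
        self.eigenvalues_ = pca.explained_variance_.copy()
        self.variance_fractions_ = pca.explained_variance_ratio_.copy()
        self.mean_flat_ = pca.mean_.copy()
        return self

    def transform(self, configs: list[LandmarkConfiguration]) -> np.ndarray:
        """Project new specimens by aligning each to the GPA mean shape."""
        rows = []
        for cfg in configs:
            res = optimal_superimposition(self.mean_shape_, cfg,
                                          allow_reflection=False)
            rows.append(res.apply(cfg.coords)[self.mask_].ravel())
        return (np.stack(rows) - self.mean_flat_) @ self.loadings_.T

    def result_(self) -> PCAResult:
        return PCAResult(eigenvalues=self.eigenvalues_,
                         component_scores=self.scores_,
                         loadings=self.loadings_,
                         variance_fractions=self.variance_fractions_)


def shape_pca(gpa: GPAResult, n_components: int | None = None) -> PCAResult:
    """Functional wrapper over :class:`ShapePCA`."""
    return ShapePCA(n_components=n_components).fit(gpa).result_()


def hull_membership(scores: np.ndarray, group: list[int],
                    query: np.ndarray, tol: float = 1e-9) -> bool:
    """Whether a 2-D query point lies inside (or on) a group's convex hull."""
    pts = np.asarray(scores, float)[list(group), :2]
    if len(pts) < 3:
        raise ValueError("hull_membership: group must have >= 3 members")
    try:
        hull = ConvexHull(pts)
    except QhullError as err:
        raise ValueError("hull_membership: group points are collinear") from err
    q = np.asarray(query, float).reshape(2)
    return bool(np.all(hull.equations[:, :2] @ q + hull.equations[:, 2] <= tol))


# ---------------------------------------------------------------------------
# full evaluation report


@dataclass
class EvaluationReport:
    """Distances and improvements for one specimen's retrodeformations."""

    deformed_distance: float
    method_distances: dict[str, float]
    percent_improvements: dict[str, float]
    reference_distances: list[float] = field(default_factory=list)
    within_reference_range: dict[str, bool] = field(default_factory=dict)
    pca_scores: dict[str, np.ndarray] | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tabular report; distances rounded to 2 decimals, improvements to 1
        (half-even), matching conventional report formatting.  Full-precision
        values stay on the dataclass."""
        rows = [{"variant": "deformed",
                 "distance": float(np.round(self.deformed_distance, 2)),
                 "percent_improvement": np.nan,
                 "within_reference_range":
                     self.within_reference_range.get("deformed", np.nan)}]
        for name in sorted(self.method_distances):
            rows.append({
                "variant": name,
                "distance": float(np.round(self.method_distances[name], 2)),
                "percent_improvement":
                    float(np.round(self.percent_improvements[name], 1)),
                "within_reference_range":
                    self.within_reference_range.get(name, np.nan)})
        return pd.DataFrame(rows)


def evaluate_retrodeformation(
        original: LandmarkConfiguration,
        deformed: LandmarkConfiguration,
        retro_variants: dict[str, LandmarkConfiguration],
        reference_samples: list[LandmarkConfiguration] | None = None,
        pca: ShapePCA | None = None) -> EvaluationReport:
    """Score retrodeformed variants against the undeformed original.

    Distances are Procrustes distances to ``original``; improvements compare
    each variant with the deformed state.  When reference samples are given
    (e.g. conspecifics or digitization replicates), their pairwise distance
    distribution is computed and each distance is flagged as falling within
    its range.  When a fitted :class:`ShapePCA` is given, all inputs are
    projected into that shape space.
    """
    d_def = procrustes_distance(original, deformed)
    dists = {name: procrustes_distance(original, cfg)
             for name, cfg in sorted(retro_variants.items())}
    improvements = {name: percent_improvement(d_def, d)
                    for name, d in dists.items()} if d_def > 0 else \
        {name: float("nan") for name in dists}
    ref = pairwise_distance_distribution(reference_samples) \
        if reference_samples else []
    within = {}
    if ref:
        lo, hi = min(ref), max(ref)
        within["deformed"] = bool(lo <= d_def <= hi)
        for name, d in dists.items():
            within[name] = bool(lo <= d <= hi)
    scores = None
    if pca is not None:
        keys = ["original", "deformed"] + list(dists)
        cfgs = [original, deformed] + [retro_variants[k] for k in dists]
        proj = pca.transform(cfgs)
        scores = {k: proj[i] for i, k in enumerate(keys)}
    return EvaluationReport(deformed_distance=d_def, method_distances=dists,
                            percent_improvements=improvements,
                            reference_distances=ref,
                            within_reference_range=within,
                            pca_scores=scores)
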