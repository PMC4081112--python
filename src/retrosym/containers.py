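"""Core data containers for landmark-based shape analysis.

A specimen is represented by a :class:`LandmarkConfiguration` — an ordered,
labelled set of 3-D points with a per-landmark availability mask.  Bilateral
(object) symmetry structure is carried separately by a
:class:`BilateralPairing`, which lists left/right landmark pairs and unpaired
midline landmarks.  Planes are stored in Hessian normal form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LandmarkConfiguration:
    """Ordered, labelled 3-D landmark set for one specimen.

    Parameters
    ----------
    labels : sequence of str
        Unique landmark identifiers, in digitisation order.
    coords : (n, 3) array of float
        Cartesian coordinates in any consistent length unit.  Rows of absent
        landmarks may hold NaN.
    present_mask : (n,) bool array, optional
        Availability flag per landmark; defaults to all present.
    """

    labels: list[str]
    coords: np.ndarray
    present_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.labels) != self.coords.shape[0]:
            raise ValueError("labels and coords length mismatch")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate landmark labels: {dupes}")
        if self.present_mask is None:
            self.present_mask = np.ones(len(self.labels), dtype=bool)
        else:
            self.present_mask = np.asarray(self.present_mask, dtype=bool)
            if self.present_mask.shape != (len(self.labels),):
                raise ValueError("present_mask must have one flag per landmark")
        if not np.all(np.isfinite(self.coords[self.present_mask])):
            raise ValueError("non-finite coordinates at present landmarks")

    @property
    def n_landmarks(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"landmark label not found: {label!r}") from None

    def with_coords(self, coords: np.ndarray,
                    present_mask: np.ndarray | None = None) -> "LandmarkConfiguration":
        """Copy carrying new coordinates (and optionally a new mask)."""
        return LandmarkConfiguration(
            list(self.labels), np.array(coords, dtype=float),
            self.present_mask.copy() if present_mask is None else present_mask)

    def copy(self) -> "LandmarkConfiguration":
        return self.with_coords(self.coords.copy())


@dataclass
class BilateralPairing:
    """Left/right landmark pairs plus midline labels defining object symmetry."""

    pairs: list[tuple[str, str]]
    midline: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pairs = [(str(l), str(r)) for l, r in self.pairs]
        self.midline = [str(m) for m in self.midline]
        seen: set[str] = set()
        for lab in [x for p in self.pairs for x in p] + list(self.midline):
            if lab in seen:
                raise ValueError(f"label appears more than once in pairing: {lab!r}")
            seen.add(lab)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def validate_against(self, config: LandmarkConfiguration) -> None:
        known = set(config.labels)
        missing = [lab for lab in
                   [x for p in self.pairs for x in p] + list(self.midline)
                   if lab not in known]
        if missing:
            raise ValueError(f"pairing references unknown labels: {missing}")

    def indices(self, config: LandmarkConfiguration
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(left_idx, right_idx, midline_idx) into ``config.coords``."""
        self.validate_against(config)
        li = np.array([config.index_of(l) for l, _ in self.pairs], dtype=int)
        ri = np.array([config.index_of(r) for _, r in self.pairs], dtype=int)
        mi = np.array([config.index_of(m) for m in self.midline], dtype=int)
        return li, ri, mi


@dataclass
class Plane:
    """Oriented plane in Hessian normal form: {x : normal·x = offset}."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        n = np.linalg.norm(self.normal)
        if not np.isfinite(n) or n == 0:
            raise ValueError("plane normal must be a finite nonzero vector")
        self.normal = self.normal / n
        self.offset = float(self.offset)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.normal - self.offset

    def flipped(self) -> "Plane":
        return Plane(-self.normal, -self.offset)


@dataclass
class Mesh:
    """Triangulated surface: (v, 3) vertices and (f, 3) integer faces."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (v, 3)")
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")


@dataclass
class SuperimpositionResult:
    """Optimal similarity transform of one configuration onto another.

    ``moving`` maps onto ``target`` as ``scale * coords @ rotation + translation``.
    ``distance`` is the Procrustes distance: the square root of the minimised
    residual sum of squares between the unit-centroid-size, centred
    configurations.
    """

    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    distance: float
    used_reflection: bool

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(coords, float) @ self.rotation + self.translation


@dataclass
class GPAResult:
    """Generalized Procrustes analysis output."""

    mean_shape: LandmarkConfiguration
    aligned: list[LandmarkConfiguration]
    iterations: int
    converged: bool


@dataclass
class SymmetrizationOutput:
    """Result of a symmetrization method applied to one configuration."""

    config: LandmarkConfiguration
    asymmetry_before: float
    asymmetry_after: float
    method_tag: str
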