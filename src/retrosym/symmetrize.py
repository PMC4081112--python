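"""Symmetrization by reflection & averaging.

The baseline retrodeformation technique: mirror the configuration through a
plane, exchange left/right labels, rigidly align the mirrored copy onto the
original, and average corresponding landmarks.  The average is then exactly
symmetrized about its own best-fit midplane (a floating-point-level
correction when the alignment is optimal), so the output always has object
symmetry to machine precision.

Reflection completion of missing bilateral landmarks lives here too.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .containers import (
    BilateralPairing,
    LandmarkConfiguration,
    Plane,
    SymmetrizationOutput,
)
from .geometry import (
    canonical_frame,
    fit_midline_plane,
    optimal_superimposition,
    procrustes_distance,
    reflect_across_plane,
)

__all__ = [
    "reflect_and_relabel",
    "reflection_average",
    "impute_from_reflection",
    "asymmetry_score",
    "ReflectionSymmetrizer",
    "enforce_exact_symmetry",
]

_MIRROR_X = np.diag([-1.0, 1.0, 1.0])


def _pair_permutation(config: LandmarkConfiguration,
                      pairing: BilateralPairing) -> np.ndarray:
    """Index permutation exchanging left and right labels within each pair."""
    li, ri, _ = pairing.indices(config)
    perm = np.arange(config.n_landmarks)
    perm[li], perm[ri] = ri, li
    return perm


def reflect_and_relabel(config: LandmarkConfiguration,
                        pairing: BilateralPairing,
                        plane: Plane) -> LandmarkConfiguration:
    """Mirror a configuration across ``plane`` and swap paired labels.

    The output keeps the input label ordering; midline and unpaired labels
    keep their own (mirrored) coordinates.  Applying the operation twice with
    the same plane restores the input exactly.
    """
    perm = _pair_permutation(config, pairing)
    coords = config.coords.copy()
    pres = config.present_mask
    coords[pres] = reflect_across_plane(config.coords[pres], plane)
    return LandmarkConfiguration(list(config.labels), coords[perm], pres[perm])


def asymmetry_score(config: LandmarkConfiguration,
                    pairing: BilateralPairing) -> float:
    """Procrustes distance between a configuration and its mirrored, relabelled copy.

    Zero exactly when the configuration has perfect object symmetry.  The
    reflection plane used is immaterial (the score is invariant to it); the
    plane x = 0 through the centroid is used.
    """
    pres = config.present_mask
    centroid = config.coords[pres].mean(axis=0)
    plane = Plane(np.array([1.0, 0.0, 0.0]), float(centroid[0]))
    mirrored = reflect_and_relabel(config, pairing, plane)
    return procrustes_distance(config, mirrored)


def enforce_exact_symmetry(config: LandmarkConfiguration,
                           pairing: BilateralPairing,
                           plane: Plane | None = None) -> LandmarkConfiguration:
    """Project a configuration onto exact mirror symmetry about ``plane``.

    In the frame in which the plane is x = 0, each bilateral pair is replaced
    by the average of the left member and the mirrored right member (and its
    mirror image), and midline landmarks are projected onto the plane.  When
    ``plane`` is None the configuration's own best-fit midplane is used.
    Landmarks outside the pairing are left untouched.
    """
    if plane is None:
        plane = fit_midline_plane(config, pairing)
    R, p0 = canonical_frame(plane)
    W = (config.coords - p0) @ R
    li, ri, mi = pairing.indices(config)
    pres = config.present_mask
    keep = pres[li] & pres[ri]
    lk, rk = li[keep], ri[keep]
    left_avg = 0.5 * (W[lk] + W[rk] @ _MIRROR_X)
    W[lk] = left_avg
    W[rk] = left_avg @ _MIRROR_X
    mk = mi[pres[mi]]
    W[mk, 0] = 0.0
    return config.with_coords(W @ R.T + p0)


def reflection_average(config: LandmarkConfiguration,
                       pairing: BilateralPairing) -> SymmetrizationOutput:
    """Symmetrize by reflection & averaging.

    The mirrored, relabelled copy is rigidly superimposed onto the original
    (no scaling: the mirror image has identical centroid size, and fitting a
    scale could absorb real signal), corresponding landmarks are averaged,
    and the average is projected onto exact symmetry about its fitted
    midplane.
    """
    if pairing.n_pairs < 3:
        raise ValueError("reflection_average: need at least 3 bilateral pairs")
    before = asymmetry_score(config, pairing)
    pres = config.present_mask
    centroid = config.coords[pres].mean(axis=0)
    plane = Plane(np.array([1.0, 0.0, 0.0]), float(centroid[0]))
    mirrored = reflect_and_relabel(config, pairing, plane)
    res = optimal_superimposition(config, mirrored,
                                  allow_reflection=False, with_scaling=False)
    coords = config.coords.copy()
    both = pres & mirrored.present_mask
    aligned = res.apply(mirrored.coords[both])
    coords[both] = 0.5 * (config.coords[both] + aligned)
    averaged = config.with_coords(coords)
    out = enforce_exact_symmetry(averaged, pairing)
    after = asymmetry_score(out, pairing)
    return SymmetrizationOutput(config=out, asymmetry_before=before,
                                asymmetry_after=after, method_tag="reflect_average")


def impute_from_reflection(config: LandmarkConfiguration,
                           pairing: BilateralPairing) -> LandmarkConfiguration:
    """Fill absent bilateral landmarks from the aligned mirrored copy.

    The mirrored, relabelled configuration is superimposed onto the original
    over the landmarks present in both; each absent landmark whose partner is
    present receives the aligned mirrored position.  Absent landmarks whose
    partners are also absent (and absent midline landmarks, which have no
    partner) are left absent with a warning.
    """
    pres = config.present_mask
    if pres.all():
        return config.copy()
    centroid = config.coords[pres].mean(axis=0)
    plane = Plane(np.array([1.0, 0.0, 0.0]), float(centroid[0]))
    mirrored = reflect_and_relabel(config, pairing, plane)
    res = optimal_superimposition(config, mirrored,
                                  allow_reflection=False, with_scaling=False)
    coords = config.coords.copy()
    mask = pres.copy()
    fillable = ~pres & mirrored.present_mask
    coords[fillable] = res.apply(mirrored.coords[fillable])
    mask[fillable] = True
    unfilled = [config.labels[i] for i in np.flatnonzero(~mask)]
    if unfilled:
        warnings.warn("impute_from_reflection: could not impute landmarks "
                      f"(partner also absent or no partner): {unfilled}")
    return config.with_coords(coords, mask)


class ReflectionSymmetrizer(BaseEstimator):
    """Reflection-&-averaging symmetrization as a transformer.

    Parameters
    ----------
    pairing : BilateralPairing
        Left/right pairs and midline labels defining object symmetry.

    Attributes
    ----------
    output_ : SymmetrizationOutput
    asymmetry_before_, asymmetry_after_ : float
    """

    def __init__(self, pairing: BilateralPairing = None):
        self.pairing = pairing

    def fit(self, config: LandmarkConfiguration) -> "ReflectionSymmetrizer":
        if self.pairing is None:
            raise ValueError("ReflectionSymmetrizer requires a pairing")
        self.output_ = reflection_average(config, self.pairing)
        self.asymmetry_before_ = self.output_.asymmetry_before
        self.asymmetry_after_ = self.output_.asymmetry_after
        return self

    def transform(self, config: LandmarkConfiguration) -> LandmarkConfiguration:
        return reflection_average(config, self.pairing).config

    def fit_transform(self, config: LandmarkConfiguration) -> LandmarkConfiguration:
        return self.fit(config).output_.config
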