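"""Similarity measures between Hill and Adair-Klotz distribution functions.

The Adair-Klotz distribution is projected onto the common state space
(the images of the Hill states) and compared with the Hill distribution
through three measures:

* ``delta`` — the main similarity, the Bhattacharyya overlap
  ``sum_i sqrt(P_H(i) * P_A(image(i)))``.  It is 1 exactly when the
  Adair-Klotz distribution matches the Hill distribution on the common
  states and places no mass on intermediates, and 0 when all Adair-Klotz
  mass sits on intermediate-containing states.
* ``delta_bar`` — the complement occupancy, the total Adair-Klotz
  probability on states containing at least one intermediate.
* ``delta_tilde`` — the shape similarity, the Bhattacharyya overlap after
  renormalizing the projected Adair-Klotz distribution to unit mass.

The three are linked by the exact factorization

    delta = sqrt(1 - delta_bar) * delta_tilde,

separating "how much mass leaks into intermediates" from "how similar the
shapes are on the common states".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .master_equation import DistributionTrajectory
from .state_space import CommonStateMap

__all__ = [
    "ProjectedDistribution",
    "SimilarityTriple",
    "SimilarityTrajectory",
    "project_onto_common",
    "complement_mass",
    "main_similarity",
    "renormalize_on_image",
    "shape_similarity",
    "similarity_trajectory",
]

#: image masses below this are treated as "shape undefined"
_MASS_FLOOR = 1e-12


@dataclass(frozen=True)
class ProjectedDistribution:
    """Adair-Klotz probability mass carried by each Hill state's image."""

    values: np.ndarray
    image_mass: float


@dataclass(frozen=True)
class SimilarityTriple:
    t: float
    delta: float
    delta_bar: float
    delta_tilde: float


@dataclass(frozen=True)
class SimilarityTrajectory:
    """Time courses of the three similarity measures on a common grid."""

    times: np.ndarray
    delta: np.ndarray
    delta_bar: np.ndarray
    delta_tilde: np.ndarray

    def __iter__(self):
        for t, d, db, dt in zip(self.times, self.delta, self.delta_bar, self.delta_tilde):
            yield SimilarityTriple(float(t), float(d), float(db), float(dt))

    def __len__(self) -> int:
        return len(self.times)


def _clip01(p: np.ndarray) -> np.ndarray:
    # guard square roots against -1e-15 round-off
    return np.clip(np.asarray(p, dtype=float), 0.0, 1.0)


def project_onto_common(p_adair: np.ndarray, cmap: CommonStateMap) -> ProjectedDistribution:
    """Restrict an Adair-Klotz distribution to the image states."""
    values = _clip01(p_adair)[cmap.adair_image_indices]
    return ProjectedDistribution(values, float(values.sum()))


def complement_mass(p_adair: np.ndarray, cmap: CommonStateMap) -> float:
    """delta_bar: total probability on intermediate-containing states."""
    if len(cmap.complement_indices) == 0:
        return 0.0
    return float(_clip01(p_adair)[list(cmap.complement_indices)].sum())


def main_similarity(p_hill: np.ndarray, p_adair: np.ndarray, cmap: CommonStateMap) -> float:
    """delta: Bhattacharyya overlap of the two distributions on common states."""
    proj = project_onto_common(p_adair, cmap)
    ph = _clip01(p_hill)[cmap.hill_indices]
    return float(np.sqrt(ph * proj.values).sum())


def renormalize_on_image(p_adair: np.ndarray, cmap: CommonStateMap) -> np.ndarray:
    """Projected Adair-Klotz distribution rescaled to unit mass.

    Raises
    ------
    ZeroDivisionError
        If essentially no mass lies on the image states, so the shape of
        the projected distribution is undefined.
    """
    proj = project_onto_common(p_adair, cmap)
    if proj.image_mass <= _MASS_FLOOR:
        raise ZeroDivisionError(
            "image mass is ~0: the projected distribution has no defined shape"
        )
    return proj.values / proj.image_mass


def shape_similarity(p_hill: np.ndarray, p_adair: np.ndarray, cmap: CommonStateMap) -> float:
    """delta_tilde: overlap of the Hill and renormalized projected shapes."""
    ph = _clip01(p_hill)[cmap.hill_indices]
    return float(np.sqrt(ph * renormalize_on_image(p_adair, cmap)).sum())


def similarity_trajectory(
    hill_traj: DistributionTrajectory,
    adair_traj: DistributionTrajectory,
    cmap: CommonStateMap,
) -> SimilarityTrajectory:
    """Evaluate (delta, delta_bar, delta_tilde) along matching time grids."""
    if len(hill_traj.times) != len(adair_traj.times) or not np.allclose(
        hill_traj.times, adair_traj.times, rtol=0, atol=0
    ):
        raise ValueError("trajectories must share an identical time grid")
    n = len(hill_traj.times)
    delta = np.empty(n)
    delta_bar = np.empty(n)
    delta_tilde = np.empty(n)
    for k in range(n):
        ph = hill_traj.distributions[k]
        pa = adair_traj.distributions[k]
        delta[k] = main_similarity(ph, pa, cmap)
        delta_bar[k] = complement_mass(pa, cmap)
        delta_tilde[k] = shape_similarity(ph, pa, cmap)
    return SimilarityTrajectory(np.asarray(hill_traj.times, dtype=float), delta, delta_bar, delta_tilde)
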