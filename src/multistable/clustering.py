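"""Cross-observer clustering of matching-volume centers.

Tests whether the centers of observers' matching volumes cluster more
tightly than expected when observers' statistic pairs (T_dom, C_v) and
(c_H, tau_H) are recombined at random into "virtual observers".  The null
distribution is the group-mean pairwise center distance across many virtual
observer sets; the p-value is the fraction of null group means at or below
the observed one (one-sided: clustering = small distances).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .errors import InsufficientDataError
from .observables import ObservableSet

__all__ = [
    "ObserverStats",
    "ClusterNull",
    "pairwise_center_distances",
    "make_virtual_observers",
    "cluster_null_test",
]

#: axis ranges of (i0, beta, phi_a) used to normalise center coordinates to
#: the unit cube before computing Euclidean distances
AXIS_RANGES = np.array([2.0, 2.0, 1.0])


@dataclass(frozen=True)
class ObserverStats:
    """One observer/display data set: the two statistic pairs."""

    id: str
    display: str  # KD | BR | NC
    pair1: Tuple[float, float]  # (T_dom, C_v)
    pair2: Tuple[float, float]  # (c_H, tau_H)

    def __post_init__(self):
        if any(v <= 0 for v in (*self.pair1, *self.pair2)):
            raise InsufficientDataError("observer statistics must be positive")

    def to_observables(self) -> ObservableSet:
        return ObservableSet(t_dom=self.pair1[0], c_v=self.pair1[1],
                             c_h=self.pair2[0], tau_h=self.pair2[1])


@dataclass
class ClusterNull:
    observed_group_mean: float
    null_group_means: np.ndarray
    p_value: float

    def p_report(self) -> str:
        if self.p_value < 1.0 / self.null_group_means.size:
            return f"< {1.0 / self.null_group_means.size:g}"
        return f"{self.p_value:g}"


def pairwise_center_distances(centers: Sequence[np.ndarray]) -> np.ndarray:
    """Euclidean norms between all unordered pairs of volume centers.

    Coordinates (i0, beta, phi_a) are normalised by the axis ranges
    ([0,2], [0,2], [0,1] -> unit cube) so the three parameters weigh
    equally.  Returns n*(n-1)/2 distances.
    """
    pts = np.asarray(centers, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise InsufficientDataError("need at least 2 centers")
    scaled = pts / AXIS_RANGES
    n = scaled.shape[0]
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            out.append(np.linalg.norm(scaled[i] - scaled[j]))
    return np.array(out)


def make_virtual_observers(real: Sequence[ObserverStats], n_sets: int,
                           set_size: int, seed: int = 0
                           ) -> List[List[ObserverStats]]:
    """Recombine real observers' statistic pairs into virtual observer sets.

    Each virtual observer draws its (T_dom, C_v) pair from one randomly
    chosen real observer and its (c_H, tau_H) pair from an independently
    chosen real observer, with replacement.
    """
    if len(real) < 1:
        raise InsufficientDataError("need at least one real observer")
    rng = np.random.default_rng(seed)
    sets = []
    for s in range(n_sets):
        members = []
        for v in range(set_size):
            o1 = real[int(rng.integers(len(real)))]
            o2 = real[int(rng.integers(len(real)))]
            members.append(ObserverStats(id=f"virtual-{s}-{v}",
                                         display=o1.display,
                                         pair1=o1.pair1, pair2=o2.pair2))
        sets.append(members)
    return sets


def cluster_null_test(real_centers: Sequence[np.ndarray],
                      virtual_center_sets: Sequence[Sequence[np.ndarray]]
                      ) -> ClusterNull:
    """One-sided permutation test of center clustering.

    ``real_centers`` are the matching-volume centers of the real observers;
    each element of ``virtual_center_sets`` holds the centers obtained for
    one set of virtual observers (each passed through the same grid scan).
    The p-value is the fraction of null group-mean distances less than or
    equal to the observed group mean.
    """
    if len(virtual_center_sets) == 0:
        raise InsufficientDataError("empty null: no virtual observer sets")
    observed = float(np.mean(pairwise_center_distances(real_centers)))
    null = np.array([float(np.mean(pairwise_center_distances(s)))
                     for s in virtual_center_sets])
    p = float(np.mean(null <= observed))
    return ClusterNull(observed_group_mean=observed, null_group_means=null,
                       p_value=p)
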