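"""Spherical rotation ("spin") null models for cortical map comparisons.

Parcel centroids live on the unit sphere, one sphere per hemisphere, with
left-hemisphere coordinates stored as the mirror image (-x, y, z) of their
homotopic right-hemisphere positions.  Each spin draws three random angles
(a, b, c) and rotates both hemispheres by the same matrix in this shared
frame; because the mirror relation is encoded in the coordinates, this is
exactly the "flip the sign of the angles about the y and z axes for the
other hemisphere" rule expressed in per-hemisphere standard frames
(conjugation by the mirror), and it preserves hemispheric symmetry:
homotopic parcels receive homotopic assignments.  Rotated regions are then
matched back to
the original regions of the same hemisphere by Euclidean distance,
greedily and without replacement, processing rotated regions in descending
order of their mean distance to all unrotated regions (the hardest-to-place
regions are assigned first).  Every spin is therefore a hemisphere-
preserving bijection of region indices, and a spun map is a permutation of
the original values - spatial contiguity is approximately preserved while
the map's value multiset is exact.

Angles are drawn uniformly on [0, 2*pi) per axis.  Three uniform Euler
angles are not uniform on SO(3); this follows the cited rotation
convention, not SO(3) uniformity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._stats import PermutationResult, permutation_result


@dataclass
class SpinNull:
    """Index table of spins: row k is a bijection; spun = values[perm[k]]."""

    permutations: np.ndarray  # (n_perm, n_regions) int
    angles: np.ndarray  # (n_perm, 3) radians
    seed: int | None = None

    @property
    def n_perm(self) -> int:
        return self.permutations.shape[0]


def _rotation_matrix(a: float, b: float, c: float) -> np.ndarray:
    """R = Rz(c) @ Ry(b) @ Rx(a)."""
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return rz @ ry @ rx


def greedy_match(original: np.ndarray, rotated: np.ndarray) -> np.ndarray:
    """Greedy nearest-neighbour assignment of rotated to original regions.

    Rotated regions are processed in descending order of their mean
    Euclidean distance to all original regions; each is assigned the
    nearest original region not yet taken.  Distance ties break by region
    index order (argmin/argsort are stable on first occurrence).

    Returns ``assign`` with ``assign[i] = j``: rotated region i lands on
    original slot j.
    """
    diff = rotated[:, None, :] - original[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    order = np.argsort(-dist.mean(axis=1), kind="stable")
    n = original.shape[0]
    taken = np.zeros(n, dtype=bool)
    assign = np.full(n, -1, dtype=int)
    for i in order:
        row = np.where(taken, np.inf, dist[i])
        j = int(np.argmin(row))
        assign[i] = j
        taken[j] = True
    return assign


def generate_spins(
    geometry, n_perm: int, seed: int | None = None
) -> SpinNull:
    """Random rotations of the parcellation, matched back region-to-region.

    ``geometry`` needs ``coords`` (n, 3 unit vectors) and ``hemispheres``
    (array of 'L'/'R').  With a single hemisphere the mirrored-angle step
    is skipped with a warning.
    """
    coords = np.asarray(geometry.coords, dtype=float)
    hemis = np.asarray(geometry.hemispheres)
    rng = np.random.default_rng(seed)
    left = np.flatnonzero(hemis == "L")
    right = np.flatnonzero(hemis == "R")
    if left.size == 0 or right.size == 0:
        warnings.warn(
            "single-hemisphere geometry: hemisphere mirroring skipped", stacklevel=2
        )
    n = coords.shape[0]
    perms = np.empty((n_perm, n), dtype=int)
    angles = rng.uniform(0.0, 2 * np.pi, size=(n_perm, 3))
    groups = (
        (left, right) if left.size and right.size else (np.arange(n),)
    )
    for k in range(n_perm):
        # one matrix in the shared frame = mirrored angles in per-hemisphere
        # frames (see module docstring)
        R = _rotation_matrix(*angles[k])
        perm = np.empty(n, dtype=int)
        for idx in groups:
            rotated = coords[idx] @ R.T
            assign = greedy_match(coords[idx], rotated)
            # rotated region i lands on slot assign[i]; the spun map reads
            # spun[slot] = values[i]
            perm[idx[assign]] = idx
        perms[k] = perm
    return SpinNull(permutations=perms, angles=angles, seed=seed)


def map_correlation(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Pearson correlation of two aligned region-level maps."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share the region axis")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant map: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def p_spin(
    map_a: np.ndarray,
    map_b: np.ndarray,
    spins: SpinNull,
    alternative: str = "two_sided",
    seed: int | None = None,
) -> PermutationResult:
    """Spin-test p for the correlation between two region-level maps.

    The null correlates ``map_a`` with spun versions of ``map_b``.
    ``alternative``: "two_sided" (default), "greater" or "less".
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    observed = map_correlation(a, b)
    spun = b[spins.permutations]  # (n_perm, n)
    am = a - a.mean()
    sm = spun - spun.mean(axis=1, keepdims=True)
    null = (sm @ am) / (
        np.linalg.norm(sm, axis=1) * np.linalg.norm(am)
    )
    direction = {"two_sided": "most_extreme", "greater": "high", "less": "low"}[
        alternative
    ]
    return permutation_result(
        "map_correlation", observed, null, direction, seed if seed is not None else spins.seed,
        alternative=alternative,
    )
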