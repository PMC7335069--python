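"""Spherical parcel geometry and smooth regional profiles.

Parcels are quasi-uniform points on the unit sphere, one Fibonacci lattice
per hemisphere with the right hemisphere at x > 0 and the left hemisphere
mirrored across the x = 0 plane.  Smooth regional maps are built from real
spherical harmonics of low degree (<= 4 by default) evaluated at the
parcel coordinates, which yields the spatially autocorrelated regime that
spin-test nulls are designed for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import sph_harm_y

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class DegenerateGeometryError(ValueError):
    """Too few parcels per hemisphere for a meaningful parcellation."""


@dataclass
class ParcellationGeometry:
    region_ids: list[str]
    hemispheres: np.ndarray  # 'L' / 'R'
    coords: np.ndarray  # (n, 3) unit vectors

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def hemisphere(self, which: str) -> "ParcellationGeometry":
        mask = self.hemispheres == which
        return ParcellationGeometry(
            region_ids=[r for r, m in zip(self.region_ids, mask) if m],
            hemispheres=self.hemispheres[mask],
            coords=self.coords[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region_ids,
                "hemi": self.hemispheres,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParcellationGeometry":
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
        return cls(
            region_ids=[str(r) for r in df["region"]],
            hemispheres=df["hemi"].to_numpy(dtype=object),
            coords=coords,
        )


def generate_geometry(n_per_hemisphere: int, seed: int | None = None) -> ParcellationGeometry:
    """Mirrored Fibonacci-lattice parcellation with ``2 n`` regions.

    Each hemisphere's cortical sheet is modelled as its own full unit
    sphere (as in template spherical surface projections): the right
    hemisphere is a Fibonacci lattice covering the whole sphere and the
    left hemisphere is its mirror image (-x, y, z).  ``seed`` applies a
    random azimuthal offset so distinct seeds give distinct (but equally
    uniform) parcellations.
    """
    n = int(n_per_hemisphere)
    if n < 10:
        raise DegenerateGeometryError(
            f"n_per_hemisphere={n} < 10 gives a degenerate parcellation"
        )
    i = np.arange(n)
    cos_t = 1.0 - 2.0 * (i + 0.5) / n  # full sphere
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = i * GOLDEN_ANGLE
    if seed is not None:
        phi = phi + np.random.default_rng(seed).uniform(0, 2 * np.pi)
    right = np.column_stack([cos_t, sin_t * np.cos(phi), sin_t * np.sin(phi)])
    right /= np.linalg.norm(right, axis=1, keepdims=True)
    left = right * np.array([-1.0, 1.0, 1.0])
    coords = np.vstack([left, right])
    ids = [f"L{i + 1:03d}" for i in range(n)] + [f"R{i + 1:03d}" for i in range(n)]
    hemis = np.array(["L"] * n + ["R"] * n, dtype=object)
    return ParcellationGeometry(region_ids=ids, hemispheres=hemis, coords=coords)


def real_sph_harm_basis(coords: np.ndarray, max_degree: int = 4) -> np.ndarray:
    """Real spherical harmonics of degree 1..max_degree at unit vectors.

    Returns (n_points, n_functions); the constant degree-0 term is
    excluded so every basis function has zero spherical mean.
    """
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    theta = np.arccos(np.clip(z, -1.0, 1.0))  # polar
    phi = np.arctan2(y, x)  # azimuth
    cols = []
    for ell in range(1, max_degree + 1):
        for m in range(0, ell + 1):
            Y = sph_harm_y(ell, m, theta, phi)
            if m == 0:
                cols.append(Y.real)
            else:
                cols.append(np.sqrt(2) * (-1) ** m * Y.real)
                cols.append(np.sqrt(2) * (-1) ** m * Y.imag)
    return np.column_stack(cols)


def smooth_maps(
    coords: np.ndarray,
    n_maps: int,
    rng: np.random.Generator,
    max_degree: int = 4,
    orthogonalize: bool = True,
) -> np.ndarray:
    """Random smooth standardized regional profiles (columns).

    Each map is a random linear combination of real spherical harmonics of
    degree <= ``max_degree``; maps are optionally QR-orthogonalized across
    regions and each is standardized to mean 0, sample SD 1.
    """
    basis = real_sph_harm_basis(coords, max_degree)
    maps = basis @ rng.standard_normal((basis.shape[1], n_maps))
    if orthogonalize and n_maps > 1:
        maps, _ = np.linalg.qr(maps)
    maps = maps - maps.mean(axis=0)
    maps = maps / maps.std(axis=0, ddof=1)
    return maps


def standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)
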