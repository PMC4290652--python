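"""Solvent-accessible surface area and the interface-area baseline ΔASA.

ΔASA = (ASA₁ + ASA₂ − ASA_C) / 2: half the solvent-accessible surface
buried when the two binding units form the complex.  It is the classical
size feature against which the B-factor features are benchmarked, and
avgΔASA = ΔASA / log(min_r + 1) is its size-normalized variant.

SASA itself is computed with a Shrake–Rupley scheme: each atom's sphere
(vdW radius + probe) is sampled on a deterministic golden-spiral lattice
and a sample point counts as accessible when no neighbouring atom's
probe-inflated sphere covers it.  The lattice is fixed, so results are
exactly reproducible for a given point count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .bfactor_features import min_r
from .structure_io import ComplexPair

__all__ = ["SasaResult", "sasa", "delta_asa", "sphere_lattice"]

DEFAULT_PROBE = 1.4      # Å, water probe
DEFAULT_N_POINTS = 960   # sphere sample points per atom


@dataclass
class SasaResult:
    total: float
    per_atom: np.ndarray
    probe_radius: float
    n_sphere_points: int


def sphere_lattice(n: int) -> np.ndarray:
    """n approximately uniform unit-sphere points (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def sasa(coords: np.ndarray, radii: np.ndarray,
         probe_radius: float = DEFAULT_PROBE,
         n_sphere_points: int = DEFAULT_N_POINTS) -> SasaResult:
    """Shrake–Rupley SASA of a set of spheres (Å²).

    ``radii`` are van der Waals radii; each is inflated by the probe
    radius.  Per-atom areas are ``(exposed fraction) · 4π(r+p)²``.
    """
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n, 3)")
    n = len(coords)
    big = radii + probe_radius
    lattice = sphere_lattice(n_sphere_points)
    tree = cKDTree(coords)
    per_atom = np.zeros(n)
    max_big = big.max()
    for i in range(n):
        neigh = [j for j in tree.query_ball_point(coords[i], big[i] + max_big)
                 if j != i]
        pts = coords[i] + big[i] * lattice
        if neigh:
            nb = np.array(neigh, dtype=int)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            r2 = (big[nb] ** 2)[None, :]
            # a sample point exactly on a neighbour's surface is shared;
            # assign it to the lower-index atom so it is counted once
            eps = 1e-9 * r2
            on_surface = np.abs(d2 - r2) <= eps
            buried = ((d2 < r2 - eps) | (on_surface & (nb < i)[None, :])).any(axis=1)
            exposed = int((~buried).sum())
        else:
            exposed = n_sphere_points
        per_atom[i] = 4.0 * math.pi * big[i] ** 2 * exposed / n_sphere_points
    return SasaResult(total=float(per_atom.sum()), per_atom=per_atom,
                      probe_radius=probe_radius, n_sphere_points=n_sphere_points)


def delta_asa(pair: ComplexPair,
              probe_radius: float = DEFAULT_PROBE,
              n_sphere_points: int = DEFAULT_N_POINTS,
              log_base: float = math.e) -> tuple[float, float]:
    """(ΔASA, avgΔASA) of a complex, in Å².

    ΔASA = (ASA₁ + ASA₂ − ASA_C)/2 is non-negative up to sampling noise
    and zero for units that do not touch.
    """
    ca = pair.unit_a.coords
    cb = pair.unit_b.coords
    ra = pair.unit_a.vdw_radii
    rb = pair.unit_b.vdw_radii
    asa1 = sasa(ca, ra, probe_radius, n_sphere_points).total
    asa2 = sasa(cb, rb, probe_radius, n_sphere_points).total
    asac = sasa(np.vstack([ca, cb]), np.concatenate([ra, rb]),
                probe_radius, n_sphere_points).total
    dasa = (asa1 + asa2 - asac) / 2.0
    denom = math.log(min_r(pair) + 1.0, log_base)
    return dasa, dasa / denom
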