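"""β contacts and interfacial-atom selection.

A β contact between atoms *i* (unit A) and *j* (unit B) requires three
conditions to hold simultaneously:

1. distance: ``d(i, j) < Td + vdw(i) + vdw(j)``;
2. Voronoi: the cells of *i* and *j* share a facet in the Voronoi diagram
   of the whole complex;
3. β-skeleton: the forbidden region of the pair is empty — no third atom
   *k* sees the segment *ij* under an angle ``∠ikj ≥ ∠β``.

With the default ``∠β = 90°`` condition 3 is the Gabriel-graph test: no
atom may lie inside the sphere having *ij* as diameter.  β contacts are a
sparse, occlusion-aware subset of plain distance contacts; an atom is
*interfacial* when it has at least one cross-unit β contact and, together
with its covalently-bonded nearby atoms (within two bond steps), carries
more than two such contacts — the "local contact" rule that discards
isolated touches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .structure_io import ComplexPair, covalent_nearby

__all__ = [
    "ContactParams",
    "ContactRecord",
    "voronoi_facet_pairs",
    "forbidden_region_empty",
    "beta_contacts",
    "interfacial_atoms",
]

#: deterministic symbolic perturbation applied to Voronoi input (Å)
DEGENERACY_JITTER = 1e-9


@dataclass
class ContactParams:
    """Tunable thresholds of the β-contact definition.

    ``td`` is the distance slack added to the summed van der Waals radii
    (Å); ``beta_angle`` is ∠β in degrees — 90° makes the forbidden region
    the empty diametral sphere (Gabriel graph).
    """

    td: float = 2.8
    beta_angle: float = 90.0

    def __post_init__(self) -> None:
        if self.td <= 0:
            raise ValueError("Td must be positive")
        if not 0.0 < self.beta_angle <= 180.0:
            raise ValueError("beta_angle must be in (0, 180]")


@dataclass
class ContactRecord:
    """One cross-unit atom pair that passed the distance prefilter."""

    atom_i: int
    atom_j: int
    distance: float
    passed_distance: bool
    shared_voronoi_facet: bool
    forbidden_region_empty: bool

    @property
    def is_beta_contact(self) -> bool:
        return (self.passed_distance and self.shared_voronoi_facet
                and self.forbidden_region_empty)


def voronoi_facet_pairs(coords: np.ndarray) -> set[tuple[int, int]]:
    """Pairs of points whose Voronoi cells share a facet of positive area.

    Computed through Delaunay duality: in general position, two Voronoi
    cells share a positive-area facet exactly when the points are joined
    by a Delaunay edge.  General position is enforced by a deterministic
    ~1e-9 Å perturbation keyed to point order, which resolves cospherical
    degeneracies (and hence zero-area facets) reproducibly.  (Qhull's
    direct Voronoi ridge enumeration drops some hull-adjacent ridges, so
    the dual route is also the more faithful one.)
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 5:
        raise ValueError("need at least 5 points for a 3D Voronoi diagram")
    rank = np.linalg.matrix_rank(coords - coords.mean(axis=0), tol=1e-9)
    if rank < 3:
        raise ValueError("degenerate geometry: points are coplanar")
    idx = np.arange(len(coords), dtype=float)[:, None]
    jitter = DEGENERACY_JITTER * np.sin(idx * np.array([1.0, 2.0, 3.0]) + idx**2)
    tri = Delaunay(coords + jitter)
    pairs: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(4):
            for b in range(a + 1, 4):
                p, q = int(simplex[a]), int(simplex[b])
                pairs.add((min(p, q), max(p, q)))
    return pairs


def forbidden_region_empty(i: int, j: int, coords: np.ndarray,
                           beta_angle: float = 90.0,
                           tree: cKDTree | None = None) -> bool:
    """True iff no third atom k satisfies ``∠ikj ≥ beta_angle``.

    Any blocker k with ``∠ikj ≥ θ`` lies within ``|ij|/sin θ`` of atom i
    (law of sines), so only that neighbourhood is scanned when a k-d tree
    is supplied.
    """
    if i == j:
        raise ValueError("i and j must differ")
    coords = np.asarray(coords, dtype=float)
    pi, pj = coords[i], coords[j]
    dij = float(np.linalg.norm(pi - pj))
    theta = math.radians(beta_angle)
    if tree is not None:
        candidates = tree.query_ball_point(pi, dij / max(math.sin(theta), 1e-9) + 1e-9)
        ks = np.array([k for k in candidates if k != i and k != j], dtype=int)
    else:
        ks = np.array([k for k in range(len(coords)) if k != i and k != j], dtype=int)
    if len(ks) == 0:
        return True
    vk_i = pi - coords[ks]
    vk_j = pj - coords[ks]
    ni = np.linalg.norm(vk_i, axis=1)
    nj = np.linalg.norm(vk_j, axis=1)
    if np.any(ni < 1e-9) or np.any(nj < 1e-9):
        raise ValueError("blocker atom coincides with contact endpoint")
    cosang = np.clip((vk_i * vk_j).sum(axis=1) / (ni * nj), -1.0, 1.0)
    angles = np.arccos(cosang)
    return bool(np.all(angles < theta))


def beta_contacts(pair: ComplexPair,
                  params: ContactParams | None = None,
                  include_hetero_blockers: bool = True) -> list[ContactRecord]:
    """All cross-unit contact candidates with the three β criteria evaluated.

    One record is emitted per cross-unit atom pair passing the distance
    prefilter; the Voronoi diagram and the forbidden-region scan run on
    the union of both units' atoms, so either unit can occlude contacts of
    the other.  Hetero atoms never appear as contact partners but do act
    as blockers unless ``include_hetero_blockers`` is False.
    """
    params = params or ContactParams()
    coords = pair.coords()
    radii = pair.vdw_radii()
    candidates = pair.candidate_mask()
    n_a = pair.n_a

    blocker_ids = np.arange(len(coords)) if include_hetero_blockers \
        else np.flatnonzero(candidates)
    blocker_coords = coords[blocker_ids]

    tree_a = cKDTree(coords[:n_a])
    tree_b = cKDTree(coords[n_a:])
    max_r = radii.max()
    prefilter = tree_a.query_ball_tree(tree_b, r=params.td + 2 * max_r)

    close_pairs = []
    for ia, local_js in enumerate(prefilter):
        if not candidates[ia]:
            continue
        for jb in local_js:
            j = jb + n_a
            if not candidates[j]:
                continue
            d = float(np.linalg.norm(coords[ia] - coords[j]))
            if d < params.td + radii[ia] + radii[j]:
                close_pairs.append((ia, j, d))
    if not close_pairs:
        return []

    facet_pairs = voronoi_facet_pairs(coords)
    blocker_tree = cKDTree(blocker_coords)
    # map global -> position in blocker_coords for self-exclusion
    pos_of = {g: p for p, g in enumerate(blocker_ids)}

    records = []
    for ia, j, d in close_pairs:
        shared = (ia, j) in facet_pairs
        fr_empty = forbidden_region_empty_point(
            coords[ia], coords[j], blocker_coords,
            exclude=(pos_of.get(ia), pos_of.get(j)),
            beta_angle=params.beta_angle, tree=blocker_tree)
        records.append(ContactRecord(
            atom_i=ia, atom_j=j, distance=d,
            passed_distance=True,
            shared_voronoi_facet=shared,
            forbidden_region_empty=fr_empty,
        ))
    return records


def forbidden_region_empty_point(pi: np.ndarray, pj: np.ndarray,
                                 coords: np.ndarray,
                                 exclude: tuple[int | None, int | None] = (None, None),
                                 beta_angle: float = 90.0,
                                 tree: cKDTree | None = None) -> bool:
    """Angle-scan variant taking endpoint coordinates directly."""
    dij = float(np.linalg.norm(pi - pj))
    theta = math.radians(beta_angle)
    if tree is not None:
        cand = tree.query_ball_point(pi, dij / max(math.sin(theta), 1e-9) + 1e-9)
    else:
        cand = range(len(coords))
    ks = np.array([k for k in cand if k not in exclude], dtype=int)
    if len(ks) == 0:
        return True
    vk_i = pi - coords[ks]
    vk_j = pj - coords[ks]
    ni = np.linalg.norm(vk_i, axis=1)
    nj = np.linalg.norm(vk_j, axis=1)
    keep = (ni > 1e-9) & (nj > 1e-9)
    if not np.all(keep):
        raise ValueError("blocker atom coincides with contact endpoint")
    cosang = np.clip((vk_i * vk_j).sum(axis=1) / (ni * nj), -1.0, 1.0)
    return bool(np.all(np.arccos(cosang) < theta))


def interfacial_atoms(pair: ComplexPair,
                      contacts: Sequence[ContactRecord],
                      bond_graph: Mapping[int, set[int]] | None = None,
                      min_local_contacts: int = 2) -> dict[str, set[int]]:
    """Interfacial atoms of each unit under the local-contact rule.

    An atom qualifies iff it has ≥ 1 β contact of its own AND the β
    contacts of itself plus those of its covalently-bonded nearby atoms
    (two bond steps) number more than ``min_local_contacts``.  Returns
    global atom ids keyed by unit name ("A"/"B").
    """
    if bond_graph is None:
        bond_graph = pair.bond_graph()
    n_contacts: dict[int, int] = {}
    for rec in contacts:
        if rec.is_beta_contact:
            n_contacts[rec.atom_i] = n_contacts.get(rec.atom_i, 0) + 1
            n_contacts[rec.atom_j] = n_contacts.get(rec.atom_j, 0) + 1
    result: dict[str, set[int]] = {"A": set(), "B": set()}
    for gid, own in n_contacts.items():
        if own < 1:
            continue
        local = sum(n_contacts.get(nb, 0)
                    for nb in covalent_nearby(gid, bond_graph))
        if local > min_local_contacts:
            result[pair.unit_of(gid)].add(gid)
    return result
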