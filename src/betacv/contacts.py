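"""Beta-contact graphs.

A contact between two heavy atoms i, j is a *beta contact* when

1. their centre distance is below the sum of van der Waals radii plus a
   slack T_d (default 3.3 Å = water diameter 2.8 + 0.5),
2. they share a Voronoi facet, i.e. they are Delaunay neighbours, and
3. no third atom k subtends an angle of at least the threshold ∠β at the
   pair (the forbidden region of the edge is empty); ∠β = 90° makes the
   forbidden region the sphere on ij as diameter, ∠β = 75° a larger lens.

All three conditions use strict inequalities: a distance exactly at the
cutoff, or an angle exactly at ∠β, rejects the contact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .structure import Structure

DEFAULT_TD = 3.3
DEFAULT_BETA_ANGLE = 75.0
NEIGHBORHOOD_BETA_ANGLE = 90.0

Edge = frozenset  # frozenset of two atom ids


@dataclass(frozen=True)
class ContactParams:
    t_d: float = DEFAULT_TD
    beta_angle: float = DEFAULT_BETA_ANGLE

    def __post_init__(self):
        if self.t_d <= 0:
            raise ValueError("T_d must be positive")
        if not 0 < self.beta_angle <= 180:
            raise ValueError("beta angle must be in (0, 180]")


@dataclass(frozen=True)
class Contact:
    pair: Edge
    distance: float
    is_delaunay: bool = True
    passes_distance: bool = False
    is_beta: bool = False


@dataclass
class ContactGraph:
    structure: Structure
    params: ContactParams
    contacts: dict[Edge, Contact] = field(default_factory=dict)

    @property
    def beta_edges(self) -> set[Edge]:
        return {e for e, c in self.contacts.items() if c.is_beta}

    def distance(self, edge: Edge) -> float:
        return self.contacts[edge].distance


def delaunay_adjacency(points: np.ndarray, jitter_seed: int = 0) -> set[tuple[int, int]]:
    """Unordered index pairs sharing a Voronoi facet (3D Delaunay edges).

    Fewer than four points (or degenerate input that still fails after a
    deterministic ≤1e-6 Å jitter) fall back to the complete graph, the
    documented convention for inputs without a full-dimensional hull.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        return set()
    if n < 4:
        return {(i, j) for i in range(n) for j in range(i + 1, n)}
    try:
        tri = Delaunay(points)
    except QhullError:
        rng = np.random.default_rng(jitter_seed)
        try:
            tri = Delaunay(points + rng.uniform(-1e-6, 1e-6, points.shape))
        except QhullError:
            return {(i, j) for i in range(n) for j in range(i + 1, n)}
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for i, j in itertools.combinations(simplex, 2):
            edges.add((min(i, j), max(i, j)))
    return edges


def distance_filter(edges, coords: np.ndarray, radii: np.ndarray,
                    t_d: float = DEFAULT_TD) -> set[tuple[int, int]]:
    """Keep edges with d(i, j) strictly below r_i + r_j + T_d."""
    kept = set()
    for i, j in edges:
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < radii[i] + radii[j] + t_d:
            kept.add((min(i, j), max(i, j)))
    return kept


def angle_at_vertex(k, i, j) -> float:
    """Interior angle, in degrees, at vertex k of the triangle (i, k, j)."""
    k, i, j = (np.asarray(x, dtype=float) for x in (k, i, j))
    u, v = i - k, j - k
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("angle undefined: vertex coincides with an endpoint")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _forbidden_radius(d: float, beta_angle: float) -> float:
    """Radius of the ball around the edge midpoint that contains every point
    subtending an angle ≥ beta_angle at the edge (beta_angle ≤ 90°: lens
    circumradius R = d / (2 sin β) placed at distance R cos β from the
    midpoint, so the bound is R (1 + cos β))."""
    b = np.deg2rad(min(beta_angle, 90.0))
    r_circ = d / (2.0 * np.sin(b))
    return r_circ * (1.0 + np.cos(b)) + 1e-9


def beta_filter(edges, coords: np.ndarray, beta_angle: float,
                candidate_ids: np.ndarray | None = None) -> set[tuple[int, int]]:
    """Keep edges whose forbidden region is empty: every other atom k must
    see the pair under an angle strictly below ``beta_angle``.

    The scan covers *all* atoms of the structure (not only Delaunay
    neighbours), pre-filtered by a KD-tree ball query bounding the forbidden
    region. ``candidate_ids`` restricts which atoms can invalidate an edge
    (used to exclude nothing by default)."""
    coords = np.asarray(coords, dtype=float)
    ids = np.arange(len(coords)) if candidate_ids is None else np.asarray(candidate_ids)
    tree = cKDTree(coords[ids])
    cosb = np.cos(np.deg2rad(beta_angle))
    kept: set[tuple[int, int]] = set()
    for i, j in edges:
        pi, pj = coords[i], coords[j]
        d = np.linalg.norm(pi - pj)
        mid = 0.5 * (pi + pj)
        near = ids[tree.query_ball_point(mid, _forbidden_radius(d, beta_angle))]
        ok = True
        for k in near:
            if k == i or k == j:
                continue
            u, v = pi - coords[k], pj - coords[k]
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            if nu == 0 or nv == 0:
                ok = False  # atom exactly on an endpoint blocks the edge
                break
            if np.dot(u, v) / (nu * nv) <= cosb:  # angle >= beta_angle
                ok = False
                break
        if ok:
            kept.add((min(i, j), max(i, j)))
    return kept


def build_contact_graph(s: Structure, params: ContactParams | None = None) -> ContactGraph:
    """Delaunay → distance filter → beta filter, on all atoms of ``s``.

    Waters participate if present in ``s`` (callers keep only bound waters);
    water-water edges are discarded at the Delaunay stage. The graph stores
    every surviving Delaunay edge with its distance and flags, so the same
    object answers questions about distance-cutoff and beta contacts.
    """
    params = params or ContactParams()
    atoms = s.atoms
    coords = s.coords()
    radii = np.array([a.vdw_radius for a in atoms])
    if np.isnan(radii).any():
        raise ValueError("radii not assigned; call assign_radii_and_types first")
    is_water = np.array([a.is_water for a in atoms])
    del_edges = {
        (i, j) for i, j in delaunay_adjacency(coords)
        if not (is_water[i] and is_water[j])
    }
    dist_edges = distance_filter(del_edges, coords, radii, params.t_d)
    beta_edges = beta_filter(dist_edges, coords, params.beta_angle)
    contacts: dict[Edge, Contact] = {}
    for i, j in del_edges:
        e = frozenset((atoms[i].atom_id, atoms[j].atom_id))
        contacts[e] = Contact(
            pair=e,
            distance=float(np.linalg.norm(coords[i] - coords[j])),
            is_delaunay=True,
            passes_distance=(i, j) in dist_edges,
            is_beta=(i, j) in beta_edges,
        )
    return ContactGraph(structure=s, params=params, contacts=contacts)


def interface_contacts(g: ContactGraph, beta_only: bool = True) -> set[Edge]:
    """Contacts joining the two binding partners (waters count with neither
    side, so water-involving contacts are never interface contacts)."""
    s = g.structure
    out = set()
    for e, c in g.contacts.items():
        if beta_only and not c.is_beta:
            continue
        i, j = tuple(e)
        si, sj = s.side_of(s.atom(i)), s.side_of(s.atom(j))
        if si >= 0 and sj >= 0 and si != sj:
            out.add(e)
    return out


def water_contacts(g: ContactGraph, beta_only: bool = True) -> set[Edge]:
    """Contacts with exactly one water atom (water-water edges never exist)."""
    s = g.structure
    out = set()
    for e, c in g.contacts.items():
        if beta_only and not c.is_beta:
            continue
        i, j = tuple(e)
        if s.atom(i).is_water != s.atom(j).is_water:
            out.add(e)
    return out


def distance_cutoff_pairs(s: Structure, t_d: float = DEFAULT_TD,
                          cross_side_only: bool = False) -> set[Edge]:
    """All atom pairs meeting the distance condition alone (condition (i)),
    computed with a KD-tree rather than via the Delaunay graph."""
    atoms = s.atoms
    coords = s.coords()
    radii = np.array([a.vdw_radius for a in atoms])
    rmax = float(np.nanmax(radii))
    tree = cKDTree(coords)
    out: set[Edge] = set()
    for i, j in tree.query_pairs(2 * rmax + t_d):
        ai, aj = atoms[i], atoms[j]
        if ai.is_water and aj.is_water:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d >= ai.vdw_radius + aj.vdw_radius + t_d:
            continue
        if cross_side_only:
            si, sj = s.side_of(ai), s.side_of(aj)
            if not (si >= 0 and sj >= 0 and si != sj):
                continue
        out.add(frozenset((ai.atom_id, aj.atom_id)))
    return out
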