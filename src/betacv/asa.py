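"""Solvent-accessible surface area and the local burial terms.

Per-atom ASA is computed with a Shrake-Rupley style numerical method on a
deterministic golden-spiral point set (960 points per atom by default,
probe 1.4 Å). From the raw areas the relative-exposure/burial terms are
derived:

* atom level:     E_i = ASA_i / 50,          B_i = max(0, 1 - E_i)
  (50 Å² is roughly half the free-water sphere area 4·3.14·2.8² = 98.47 Å²)
* residue level:  E* = ASA*/max(ASA*), B* = max(0, 1 - E*) separately for
  backbone (bb: N, CA, C, O, OXT) and side chain (sc), with the maxima taken
  from extended ALA-X-ALA tripeptides,
* local terms:    E_loc = E_i · E*, B_loc = B_i · B* with * = bb or sc
  according to the atom's backbone/side-chain classification.

Waters are excluded from every ASA computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import tables
from .structure import ResidueId, Structure, split_unbound

PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960
ATOM_ASA_SCALE = 50.0  # Å², denominator of the atom-level relative ASA


def sphere_points(n: int) -> np.ndarray:
    """Deterministic, near-uniform unit-sphere points (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def shrake_rupley(coords: np.ndarray, radii: np.ndarray,
                  probe: float = PROBE_RADIUS,
                  n_points: int = N_SPHERE_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible surface area in Å²."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    pts = sphere_points(n_points)
    ext = radii + probe
    tree = cKDTree(coords)
    asa = np.zeros(n)
    rmax = ext.max()
    for i in range(n):
        surface = coords[i] + ext[i] * pts
        nbrs = [j for j in tree.query_ball_point(coords[i], ext[i] + rmax)
                if j != i]
        if nbrs:
            nb = np.array(nbrs, dtype=int)
            d2 = ((surface[:, None, :] - coords[nb][None, :, :]) ** 2).sum(-1)
            accessible = (d2 >= (ext[nb] ** 2)[None, :]).all(axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        asa[i] = frac * 4.0 * np.pi * ext[i] ** 2
    return asa


def atom_relative_terms(asa_i: float) -> tuple[float, float]:
    """Atom relative exposure E_i = ASA/50 and clamped burial B_i."""
    e = asa_i / ATOM_ASA_SCALE
    return e, max(0.0, 1.0 - e)


def residue_relative_terms(asa_bb: float, asa_sc: float, residue_name: str,
                           max_table_bb: dict[str, float] | None = None,
                           max_table_sc: dict[str, float] | None = None,
                           ) -> tuple[float, float, float, float]:
    """(E_bb, B_bb, E_sc, B_sc) relative to the residue type's maxima."""
    mx_bb = (max_table_bb or tables.MAX_ASA_BB)[residue_name]
    mx_sc = (max_table_sc or tables.MAX_ASA_SC)[residue_name]
    e_bb = asa_bb / mx_bb
    e_sc = asa_sc / mx_sc
    return e_bb, max(0.0, 1.0 - e_bb), e_sc, max(0.0, 1.0 - e_sc)


def local_terms(e_i: float, b_i: float, res_terms: tuple[float, float, float, float],
                is_backbone: bool) -> tuple[float, float]:
    """(E_loc, B_loc): atom term times its residue's bb or sc term."""
    e_bb, b_bb, e_sc, b_sc = res_terms
    if is_backbone:
        return e_i * e_bb, b_i * b_bb
    return e_i * e_sc, b_i * b_sc


@dataclass
class ASAProfile:
    """Per-atom and per-residue ASA terms of one state (bound or unbound)."""

    asa: dict[int, float] = field(default_factory=dict)         # atom id -> Å²
    e_atom: dict[int, float] = field(default_factory=dict)
    b_atom: dict[int, float] = field(default_factory=dict)
    e_loc: dict[int, float] = field(default_factory=dict)
    b_loc: dict[int, float] = field(default_factory=dict)
    residue_asa: dict[ResidueId, tuple[float, float]] = field(default_factory=dict)
    residue_terms: dict[ResidueId, tuple[float, float, float, float]] = field(
        default_factory=dict)


def compute_asa(s: Structure, probe: float = PROBE_RADIUS,
                n_points: int = N_SPHERE_POINTS) -> dict[int, float]:
    """Per-atom ASA (Å²) of the protein atoms of ``s`` (waters excluded)."""
    atoms = s.protein_atoms
    if not atoms:
        return {}
    radii = np.array([a.vdw_radius for a in atoms])
    if np.isnan(radii).any():
        raise ValueError("radii not assigned")
    areas = shrake_rupley(s.coords(atoms), radii, probe, n_points)
    return {a.atom_id: float(v) for a, v in zip(atoms, areas)}


def compute_asa_profile(s: Structure, probe: float = PROBE_RADIUS,
                        n_points: int = N_SPHERE_POINTS,
                        max_table_bb=None, max_table_sc=None) -> ASAProfile:
    """Full ASA profile (atom, residue and local terms) for one state."""
    prof = ASAProfile()
    prof.asa = compute_asa(s, probe, n_points)
    residues = s.residues()
    for rid, atoms in residues.items():
        rname = atoms[0].residue_name
        asa_bb = sum(prof.asa[a.atom_id] for a in atoms if a.is_backbone)
        asa_sc = sum(prof.asa[a.atom_id] for a in atoms if not a.is_backbone)
        prof.residue_asa[rid] = (asa_bb, asa_sc)
        prof.residue_terms[rid] = residue_relative_terms(
            asa_bb, asa_sc, rname, max_table_bb, max_table_sc)
    for a in s.protein_atoms:
        e_i, b_i = atom_relative_terms(prof.asa[a.atom_id])
        prof.e_atom[a.atom_id], prof.b_atom[a.atom_id] = e_i, b_i
        e_loc, b_loc = local_terms(e_i, b_i, prof.residue_terms[a.residue_id],
                                   a.is_backbone)
        prof.e_loc[a.atom_id], prof.b_loc[a.atom_id] = e_loc, b_loc
    return prof


def bound_unbound_profiles(s: Structure, probe: float = PROBE_RADIUS,
                           n_points: int = N_SPHERE_POINTS,
                           ) -> tuple[ASAProfile, ASAProfile]:
    """ASA profiles of the complex and of the rigid unbound split.

    The unbound profile is the union of the two partners computed in
    isolation, keyed by the same atom ids as the bound profile.
    """
    bound = compute_asa_profile(s, probe, n_points)
    unbound = ASAProfile()
    for part in split_unbound(s):
        p = compute_asa_profile(part, probe, n_points)
        unbound.asa.update(p.asa)
        unbound.e_atom.update(p.e_atom)
        unbound.b_atom.update(p.b_atom)
        unbound.e_loc.update(p.e_loc)
        unbound.b_loc.update(p.b_loc)
        unbound.residue_asa.update(p.residue_asa)
        unbound.residue_terms.update(p.residue_terms)
    return bound, unbound


def compute_max_asa_table(probe: float = PROBE_RADIUS,
                          n_points: int = N_SPHERE_POINTS,
                          ) -> tuple[dict[str, float], dict[str, float]]:
    """Recompute the reference maxima from extended ALA-X-ALA tripeptides.

    The frozen values in :mod:`betacv.tables` were produced by this function;
    GLY has no side-chain atoms and keeps a nominal 1.0 to keep divisions
    defined.
    """
    from .peptide import build_peptide

    mx_bb: dict[str, float] = {}
    mx_sc: dict[str, float] = {}
    for res in tables.STANDARD_RESIDUES:
        atoms = build_peptide(["ALA", res, "ALA"])
        coords = np.array([xyz for _, _, _, xyz in atoms])
        radii = np.array([tables.DEFAULT_RADII[(rname, name)]
                          for _, rname, name, _ in atoms])
        areas = shrake_rupley(coords, radii, probe, n_points)
        bb = sc = 0.0
        for (num, _, name, _), area in zip(atoms, areas):
            if num != 2:
                continue
            if name in tables.BACKBONE_ATOMS + tables.TERMINAL_ATOMS:
                bb += area
            else:
                sc += area
        mx_bb[res] = round(float(bb), 2)
        mx_sc[res] = round(float(sc), 2) if res != "GLY" else 1.0
    return mx_bb, mx_sc
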