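"""Atomic-contact-vector features for interfacial alanine mutations.

A mutation is represented by a 52-element vector:

* 36 elements, one per unordered pair of the 8 atomic types, aggregating the
  inverse-squared-distance contributions of the contacts that disappear (set
  M) or newly appear (set N) when the residue's side chain beyond CB is
  removed from the beta-contact graph. In the ASA-weighted variant every
  contribution is further multiplied by the local burial B_loc of both atoms,
  the water-exclusion weighting.
* 16 elements, the bound- and unbound-state local exposures E_loc of the
  atoms around the mutation site (the neighbourhood set S built from the
  ∠β = 90° graph), summed per atomic type.

Contacts between covalent-bond nearby atoms (three or fewer bond steps) are
excluded from M and N; contacts common to wild type and mutant are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import tables
from .asa import ASAProfile, bound_unbound_profiles, compute_asa_profile
from .contacts import (ContactGraph, ContactParams, Edge,
                       NEIGHBORHOOD_BETA_ANGLE, build_contact_graph,
                       distance_cutoff_pairs)
from .structure import (Structure, bond_adjacency, covalent_steps,
                        make_alanine_mutant, mutated_atoms,
                        with_bound_waters_only)

N_PAIR_FEATURES = len(tables.TYPE_PAIRS)          # 36
N_FEATURES = N_PAIR_FEATURES + 2 * tables.N_ATOM_TYPES  # 52

# B_loc assigned to bound-water oxygens in the ASA-weighted pair block:
# bound waters are interface-buried by construction and the ASA run excludes
# waters, so they are weighted as fully buried.
WATER_B_LOC = 1.0


class MutationFilterError(ValueError):
    """Mutation fails the dataset requirements (e.g. no distance-cutoff
    contact between its mutated atoms and the partner protein)."""


@dataclass
class ContactDiff:
    """Mutated (M) and new (N) contacts between wild-type and mutant graphs,
    with covalent-nearby pairs removed. Distances are center-to-center Å."""

    mutated: dict[Edge, float] = field(default_factory=dict)
    new: dict[Edge, float] = field(default_factory=dict)


def diff_contacts(g_wt: ContactGraph, g_mut: ContactGraph,
                  bonds) -> ContactDiff:
    """Edge-set difference of the two beta graphs minus covalent-nearby pairs."""
    if g_wt.params != g_mut.params:
        raise ValueError("wild-type and mutant graphs built with different params")
    adj = bonds if isinstance(bonds, dict) else bond_adjacency(bonds)
    wt, mut = g_wt.beta_edges, g_mut.beta_edges
    diff = ContactDiff()
    for e in wt - mut:
        i, j = tuple(e)
        if covalent_steps(adj, i, j, cutoff=3) > 3:
            diff.mutated[e] = g_wt.distance(e)
    for e in mut - wt:
        i, j = tuple(e)
        if covalent_steps(adj, i, j, cutoff=3) > 3:
            diff.new[e] = g_mut.distance(e)
    return diff


def _pair_index(t1: int, t2: int) -> int:
    return tables.TYPE_PAIR_INDEX[(min(t1, t2), max(t1, t2))]


def basic_acv(diff: ContactDiff, s: Structure) -> np.ndarray:
    """36-element pair block, 1/d² contributions (M positive, N negative)."""
    v = np.zeros(N_PAIR_FEATURES)
    for edges, sign in ((diff.mutated, 1.0), (diff.new, -1.0)):
        for e, d in edges.items():
            i, j = tuple(e)
            v[_pair_index(s.atom(i).atom_type, s.atom(j).atom_type)] += sign / d ** 2
    return v


def weighted_acv(diff: ContactDiff, s: Structure,
                 asa_wt: ASAProfile, asa_mut: ASAProfile) -> np.ndarray:
    """36-element pair block with B_loc·B_loc/d² contributions.

    Mutated contacts are weighted with the wild-type bound-state profile (the
    state in which they exist), new contacts with the mutant's profile.
    """
    def b_loc(profile: ASAProfile, atom_id: int) -> float:
        a = s.atom(atom_id)
        if a.is_water:
            return WATER_B_LOC
        if atom_id not in profile.b_loc:
            raise KeyError(f"no ASA term for atom {atom_id}")
        return profile.b_loc[atom_id]

    v = np.zeros(N_PAIR_FEATURES)
    for edges, sign, prof in ((diff.mutated, 1.0, asa_wt),
                              (diff.new, -1.0, asa_mut)):
        for e, d in edges.items():
            i, j = tuple(e)
            w = b_loc(prof, i) * b_loc(prof, j)
            v[_pair_index(s.atom(i).atom_type, s.atom(j).atom_type)] += sign * w / d ** 2
    return v


def neighborhood_set(s: Structure, mutated_ids: set[int], bonds,
                     g90: ContactGraph) -> set[int]:
    """Atom set S around the mutation site.

    Atoms with a ∠β = 90° beta contact to a mutated atom, plus the mutated
    atoms themselves, each expanded by its covalent-bond nearby atoms
    (three or fewer steps). Waters never enter S.
    """
    adj = bonds if isinstance(bonds, dict) else bond_adjacency(bonds)
    core = set(mutated_ids)
    for e in g90.beta_edges:
        i, j = tuple(e)
        if i in mutated_ids and not s.atom(j).is_water:
            core.add(j)
        if j in mutated_ids and not s.atom(i).is_water:
            core.add(i)

    def nearby(seed: int) -> set[int]:
        out = {seed}
        frontier = [(seed, 0)]
        while frontier:
            node, d = frontier.pop()
            if d == 3:
                continue
            for nb in adj.get(node, ()):
                if nb not in out:
                    out.add(nb)
                    frontier.append((nb, d + 1))
        return out

    full: set[int] = set()
    for a in core:
        full |= nearby(a)
    return {i for i in full if not s.atom(i).is_water}


def neighborhood_vector(S: set[int], s: Structure,
                        asa_bound: ASAProfile, asa_unbound: ASAProfile,
                        ) -> np.ndarray:
    """16-element block: per-type sums of E_loc in bound and unbound states."""
    v = np.zeros(2 * tables.N_ATOM_TYPES)
    for i in sorted(S):
        a = s.atom(i)
        t = a.atom_type - 1
        v[t] += asa_bound.e_loc[i]
        v[tables.N_ATOM_TYPES + t] += asa_unbound.e_loc[i]
    return v


@dataclass
class ACVFeature:
    """52-element representation of one alanine mutation."""

    pair_block: np.ndarray      # 36 values, fixed lexicographic pair order
    nbhd_bound: np.ndarray      # 8 values
    nbhd_unbound: np.ndarray    # 8 values

    @property
    def vector(self) -> np.ndarray:
        v = np.concatenate([self.pair_block, self.nbhd_bound, self.nbhd_unbound])
        assert len(v) == N_FEATURES
        return v


def featurize_mutation(s: Structure, residue_id, params: ContactParams | None = None,
                       mode: str = "asa", include_waters: bool = True,
                       n_sphere_points: int | None = None) -> ACVFeature:
    """Build the 52-element feature vector for one alanine mutation.

    ``s`` is the prepared wild-type complex (radii, types, bonds assigned;
    waters still present). ``mode`` selects the plain 1/d² pair block
    ("basic") or the burial-weighted one ("asa"). Raises
    :class:`MutationFilterError` when the mutated atoms have no
    distance-cutoff contact with the partner protein.
    """
    if mode not in ("basic", "asa"):
        raise ValueError("mode must be 'basic' or 'asa'")
    params = params or ContactParams()
    asa_kwargs = {} if n_sphere_points is None else {"n_points": n_sphere_points}

    removed = mutated_atoms(s, residue_id)  # validates residue / ALA / GLY
    removed_ids = {a.atom_id for a in removed}

    # dataset third requirement: a mutated atom must touch the partner protein
    side = s.side_of(removed[0])
    cross = distance_cutoff_pairs(s, params.t_d, cross_side_only=True)
    if not any(e & removed_ids for e in cross):
        raise MutationFilterError(
            f"mutated atoms of {residue_id} have no distance-cutoff contact "
            f"with the partner side ({1 - side})")

    work = with_bound_waters_only(s) if include_waters else s.with_atoms(
        s.protein_atoms)
    mut = make_alanine_mutant(work, residue_id)

    g_wt = build_contact_graph(work, params)
    g_mut = build_contact_graph(mut, params)
    diff = diff_contacts(g_wt, g_mut, s.bonds)

    protein_only = s.with_atoms(s.protein_atoms)
    if mode == "asa":
        asa_b, asa_u = bound_unbound_profiles(protein_only, **asa_kwargs)
        mut_protein = make_alanine_mutant(protein_only, residue_id)
        asa_mut = compute_asa_profile(mut_protein, **asa_kwargs)
        pair = weighted_acv(diff, s, asa_b, asa_mut)
    else:
        asa_b, asa_u = bound_unbound_profiles(protein_only, **asa_kwargs)
        pair = basic_acv(diff, s)

    g90 = build_contact_graph(work, ContactParams(params.t_d,
                                                  NEIGHBORHOOD_BETA_ANGLE))
    S = neighborhood_set(s, removed_ids, s.bonds, g90)
    nbhd = neighborhood_vector(S, s, asa_b, asa_u)
    return ACVFeature(pair_block=pair,
                      nbhd_bound=nbhd[:tables.N_ATOM_TYPES],
                      nbhd_unbound=nbhd[tables.N_ATOM_TYPES:])


def featurize_dataset(s: Structure, mutations, params: ContactParams | None = None,
                      mode: str = "asa", include_waters: bool = True,
                      n_sphere_points: int | None = None,
                      skip_filtered: bool = True):
    """Feature matrix (n × 52) and ΔΔG vector for a list of MutationRecord.

    Mutations failing the dataset filter are skipped (with the skipped list
    returned) unless ``skip_filtered`` is false.
    """
    rows, y, kept, skipped = [], [], [], []
    for m in mutations:
        try:
            f = featurize_mutation(s, m.residue_id, params, mode,
                                   include_waters, n_sphere_points)
        except MutationFilterError:
            if not skip_filtered:
                raise
            skipped.append(m)
            continue
        rows.append(f.vector)
        y.append(m.ddg_exp)
        kept.append(m)
    X = np.array(rows).reshape(-1, N_FEATURES)
    return X, np.array(y), kept, skipped
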