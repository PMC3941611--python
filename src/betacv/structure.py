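"""Protein quaternary-structure model.

Reads PDB files (via gemmi) into a light typed-atom representation with the
chain bipartition into two binding partners, assigns van der Waals radii and
the 8-class atomic types, infers covalent topology from per-residue bond
templates, builds alanine-truncation mutants and rigid unbound splits, and
detects interface-bound crystallographic waters by hydrogen-bond counting.

Hydrogens are never stored; crystallographic waters are kept as single
oxygen atoms. Atom ids are stable across derived structures (a mutant keeps
the wild-type ids of its remaining atoms), which is what lets contact graphs
of wild type and mutant be compared as edge sets.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from . import tables

ResidueId = tuple[str, int, str]  # (chain id, sequence number, insertion code)
Bond = frozenset  # frozenset of two atom ids
HBOND_DISTANCE = 3.2   # Å, donor/acceptor heavy-atom separation
OTHER_CONTACT_DISTANCE = 4.0  # Å, "other contact" in the bound-water rule


@dataclass
class Atom:
    atom_id: int
    name: str
    element: str
    residue_name: str
    residue_id: ResidueId
    coords: np.ndarray
    vdw_radius: float = float("nan")
    atom_type: int = 0
    is_water: bool = False
    is_backbone: bool = False

    @property
    def chain(self) -> str:
        return self.residue_id[0]


@dataclass
class MutationRecord:
    residue_id: ResidueId
    wild_type: str
    ddg_exp: float

    def __post_init__(self):
        if self.wild_type in ("ALA", "GLY"):
            raise ValueError(f"alanine mutation of {self.wild_type} is not modelled")

    @property
    def is_hotspot(self) -> bool:
        return self.ddg_exp >= 2.0


@dataclass
class Structure:
    """Atoms of a two-partner protein complex plus covalent topology."""

    atoms: list[Atom]
    sides: tuple[frozenset[str], frozenset[str]]
    bonds: set[Bond] = field(default_factory=set)

    def __post_init__(self):
        self._index = {a.atom_id: a for a in self.atoms}

    def atom(self, atom_id: int) -> Atom:
        return self._index[atom_id]

    @property
    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_water]

    @property
    def waters(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_water]

    def coords(self, atoms: list[Atom] | None = None) -> np.ndarray:
        atoms = self.atoms if atoms is None else atoms
        return np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3)

    def side_of(self, atom: Atom) -> int:
        """0 or 1 for protein atoms; -1 for waters (they belong to neither)."""
        if atom.is_water:
            return -1
        return 0 if atom.chain in self.sides[0] else 1

    def residues(self) -> dict[ResidueId, list[Atom]]:
        out: dict[ResidueId, list[Atom]] = {}
        for a in self.protein_atoms:
            out.setdefault(a.residue_id, []).append(a)
        return out

    def with_atoms(self, atoms: list[Atom]) -> "Structure":
        kept = {a.atom_id for a in atoms}
        bonds = {b for b in self.bonds if b <= kept}
        return Structure(atoms=atoms, sides=self.sides, bonds=bonds)


def parse_pdb(pdb_text: str, side_spec: tuple[set[str], set[str]]) -> Structure:
    """Read PDB text into a Structure with the given partner bipartition.

    Keeps heavy atoms of the first conformer (altloc '' or 'A') in file
    order; waters become single oxygen atoms flagged ``is_water``.
    """
    side_a, side_b = frozenset(side_spec[0]), frozenset(side_spec[1])
    if side_a & side_b:
        raise ValueError("side_spec chain sets must be disjoint")
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no models in PDB input")
    model = st[0]
    atoms: list[Atom] = []
    seen_chains: set[str] = set()
    next_id = 0
    for chain in model:
        for res in chain:
            is_water = res.name in tables.WATER_RESIDUES
            for at in res:
                if at.element.is_hydrogen:
                    continue
                if at.altloc not in ("\x00", "", "A"):
                    continue
                if is_water and at.name != "O":
                    continue
                rid: ResidueId = (chain.name, res.seqid.num, res.seqid.icode.strip())
                if not is_water:
                    seen_chains.add(chain.name)
                    if chain.name not in side_a | side_b:
                        raise ValueError(
                            f"chain {chain.name!r} not covered by side_spec")
                atoms.append(Atom(
                    atom_id=next_id,
                    name=at.name,
                    element=at.element.name,
                    residue_name=res.name,
                    residue_id=rid,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    is_water=is_water,
                    is_backbone=(not is_water) and at.name in
                    tables.BACKBONE_ATOMS + tables.TERMINAL_ATOMS,
                ))
                next_id += 1
    for side in (side_a, side_b):
        missing = side - seen_chains
        if missing:
            raise ValueError(f"side chains {sorted(missing)} absent from file")
        if not any(a.chain in side for a in atoms if not a.is_water):
            raise ValueError("one side of the complex has zero atoms")
    return Structure(atoms=atoms, sides=(side_a, side_b))


def to_pdb(s: Structure) -> str:
    """Serialise a Structure to PDB text (via gemmi)."""
    st = gemmi.Structure()
    st.name = "betacv"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    last_res: dict[tuple, gemmi.Residue] = {}
    for a in s.atoms:
        cid = a.residue_id[0]
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        key = (cid, a.residue_id[1], a.residue_id[2], a.residue_name)
        if key not in last_res:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_id[1], a.residue_id[2] or " ")
            res.het_flag = "H" if a.is_water else "A"
            chains[cid].add_residue(res)
            last_res[key] = chains[cid][-1]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.coords)
        at.occ = 1.0
        last_res[key].add_atom(at)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def assign_radii_and_types(
    s: Structure,
    radii_table: dict | None = None,
    type_table: dict | None = None,
    strict: bool = True,
) -> Structure:
    """Assign van der Waals radii and 8-class atomic types in place.

    Unknown (residue, atom) combinations raise in strict mode; otherwise the
    offending atoms are dropped with a warning.
    """
    radii = tables.DEFAULT_RADII if radii_table is None else radii_table
    types = tables.DEFAULT_ATOM_TYPES if type_table is None else type_table
    kept: list[Atom] = []
    for a in s.atoms:
        key = (a.residue_name, a.name)
        if key not in radii or key not in types:
            if strict:
                raise KeyError(f"no radius/type for {key}")
            warnings.warn(f"skipping atom with unknown residue/name {key}")
            continue
        a.vdw_radius = radii[key]
        a.atom_type = types[key]
        kept.append(a)
    if len(kept) != len(s.atoms):
        return s.with_atoms(kept)
    return s


def infer_covalent_topology(s: Structure, peptide_bond_max: float = 2.0) -> set[Bond]:
    """Covalent bonds from per-residue templates plus C(i)-N(i+1) peptide
    bonds closer than ``peptide_bond_max`` Å. Waters have no bonds."""
    bonds: set[Bond] = set()
    residues = s.residues()
    by_name: dict[ResidueId, dict[str, Atom]] = {
        rid: {a.name: a for a in atoms} for rid, atoms in residues.items()
    }
    for rid, named in by_name.items():
        rname = next(iter(named.values())).residue_name
        if rname not in tables.SIDE_CHAIN_BONDS:
            continue
        for a, b in tables.residue_bond_template(rname):
            if a in named and b in named:
                bonds.add(frozenset((named[a].atom_id, named[b].atom_id)))
    # peptide bonds between residues adjacent in the file within one chain
    order = sorted(by_name, key=lambda rid: (rid[0], rid[1], rid[2]))
    for prev, nxt in zip(order, order[1:]):
        if prev[0] != nxt[0]:
            continue
        c, n = by_name[prev].get("C"), by_name[nxt].get("N")
        if c is not None and n is not None:
            if np.linalg.norm(c.coords - n.coords) <= peptide_bond_max:
                bonds.add(frozenset((c.atom_id, n.atom_id)))
    s.bonds = bonds
    return bonds


def bond_adjacency(bonds: set[Bond]) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {}
    for b in bonds:
        i, j = tuple(b)
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    return adj


def covalent_steps(bonds: set[Bond] | dict[int, set[int]], a: int, b: int,
                   cutoff: int | None = None) -> float:
    """Shortest covalent-bond path length between atoms a and b (ids);
    inf if disconnected or farther than ``cutoff`` steps."""
    if a == b:
        return 0
    adj = bonds if isinstance(bonds, dict) else bond_adjacency(bonds)
    seen = {a}
    frontier = deque([(a, 0)])
    while frontier:
        node, d = frontier.popleft()
        if cutoff is not None and d >= cutoff:
            continue
        for nb in adj.get(node, ()):
            if nb == b:
                return d + 1
            if nb not in seen:
                seen.add(nb)
                frontier.append((nb, d + 1))
    return float("inf")


def is_nearby(bonds, a: int, b: int) -> bool:
    """Covalent-bond nearby: within three covalent-bond steps."""
    return covalent_steps(bonds, a, b, cutoff=3) <= 3


def mutated_atoms(s: Structure, residue_id: ResidueId) -> list[Atom]:
    """The atoms removed by an alanine truncation: everything in the residue
    except the alanine scaffold N, CA, C, O (OXT) and CB."""
    res_atoms = [a for a in s.protein_atoms if a.residue_id == residue_id]
    if not res_atoms:
        raise KeyError(f"residue {residue_id} not in structure")
    rname = res_atoms[0].residue_name
    if rname in ("ALA", "GLY"):
        raise ValueError(f"alanine mutation of {rname} at {residue_id} rejected")
    return [a for a in res_atoms if a.name not in tables.ALANINE_SCAFFOLD]


def make_alanine_mutant(s: Structure, residue_id: ResidueId) -> Structure:
    """Alanine-truncation mutant: drop the residue's side-chain atoms beyond
    CB; all other coordinates (and atom ids) are untouched."""
    removed = {a.atom_id for a in mutated_atoms(s, residue_id)}
    return s.with_atoms([a for a in s.atoms if a.atom_id not in removed])


def split_unbound(s: Structure) -> tuple[Structure, Structure]:
    """Rigid split of the complex into its two partners; waters are dropped
    from both unbound states."""
    parts = []
    for k in (0, 1):
        atoms = [a for a in s.protein_atoms if s.side_of(a) == k]
        parts.append(s.with_atoms(atoms))
    return parts[0], parts[1]


def detect_bound_waters(s: Structure) -> set[int]:
    """Atom ids of interface-bound waters.

    A water is bound if it has at least three potential hydrogen-bond
    contacts, or exactly two plus at least two further contacts under 4 Å.
    A potential hydrogen-bond contact is an N or O protein heavy atom within
    3.2 Å of the water oxygen; water-water contacts never count.
    """
    waters = s.waters
    protein = s.protein_atoms
    if not waters or not protein:
        return set()
    tree = cKDTree(s.coords(protein))
    is_no = np.array([a.element in ("N", "O") for a in protein])
    bound: set[int] = set()
    for w in waters:
        idx = np.array(tree.query_ball_point(w.coords, OTHER_CONTACT_DISTANCE),
                       dtype=int)
        if idx.size == 0:
            continue
        d = np.linalg.norm(s.coords([protein[i] for i in idx]) - w.coords, axis=1)
        hb = (d < HBOND_DISTANCE) & is_no[idx]
        n_hb = int(hb.sum())
        n_other = int(((d < OTHER_CONTACT_DISTANCE) & ~hb).sum())
        if n_hb >= 3 or (n_hb == 2 and n_other >= 2):
            bound.add(w.atom_id)
    return bound


def with_bound_waters_only(s: Structure) -> Structure:
    """Copy of the structure keeping protein atoms plus bound waters only."""
    bound = detect_bound_waters(s)
    return s.with_atoms(
        [a for a in s.atoms if not a.is_water or a.atom_id in bound])


def read_mutation_table(path) -> list[MutationRecord]:
    """Read a delimited mutation table with columns chain, resnum, wt_res
    (3-letter code) and ddg_exp (kcal/mol); '#' starts a comment."""
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = {"chain", "resnum", "wt_res", "ddg_exp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mutation table lacks columns {sorted(missing)}")
    return [
        MutationRecord(
            residue_id=(str(row.chain), int(row.resnum), ""),
            wild_type=str(row.wt_res).upper(),
            ddg_exp=float(row.ddg_exp),
        )
        for row in df.itertuples()
    ]


def prepare(pdb_text: str, side_spec, strict: bool = True) -> Structure:
    """parse → radii/types → covalent topology, in one call."""
    s = parse_pdb(pdb_text, side_spec)
    s = assign_radii_and_types(s, strict=strict)
    infer_covalent_topology(s)
    return s
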